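"""Truth-based evaluation of a simulated cohort.

Utilities that compare pipeline output against a simulation's truth table:
held-out classifier performance (families are split in two, the model is
fitted on one half's transmission labels and evaluated on the other half),
parent-of-origin accuracy of the phased calls, and recovery of the planted
post-twinning fraction from MZ-twin discordance.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from .candidates import extract_candidates
from .config import RunConfig
from .datatypes import DNMCandidate
from .gam import TransmissionGam, features_frame
from .pedigree import PATERNAL, find_three_generation_families
from .pipeline import PipelineResult, label_candidates
from .simulate import SimResult


def truth_classes(sim: SimResult, cands: Sequence[DNMCandidate]) -> np.ndarray:
    """1 for planted germline DNMs, 0 for planted artifacts, -1 unknown."""
    out = np.full(len(cands), -1, dtype=int)
    for i, c in enumerate(cands):
        cls = sim.classify_candidate(c.proband_id, c.site.chrom, c.site.pos)
        if cls == "dnm":
            out[i] = 1
        elif cls == "artifact":
            out[i] = 0
    return out


def held_out_gam_evaluation(
    sim: SimResult,
    config: Optional[RunConfig] = None,
) -> Dict[str, float]:
    """Fit the transmission GAM on half the families, evaluate on the rest.

    Families are split deterministically by parity of their numeric index;
    the model is trained on the transmission labels of one half and its
    scores are evaluated against the simulator's truth on the other half.
    """
    from sklearn.metrics import roc_auc_score

    cfg = config or RunConfig()
    ds = sim.to_dataset()
    cands = extract_candidates(ds, ds.pedigree, cfg)
    families = {
        f.proband.id: f
        for f in find_three_generation_families(ds.pedigree, cfg.min_assay_offspring)
    }

    def fam_number(proband_id: str) -> int:
        stem = proband_id.rsplit("_", 1)[0]
        digits = "".join(ch for ch in stem if ch.isdigit())
        return int(digits) if digits else 0

    train_cands = [c for c in cands if fam_number(c.proband_id) % 2 == 0]
    test_cands = [c for c in cands if fam_number(c.proband_id) % 2 == 1]
    labels = label_candidates(train_cands, families, ds, cfg)
    model = TransmissionGam.from_candidates(train_cands, labels, cfg.gam_spline_df)
    res = model.fit(select_penalty=cfg.gam_select_penalty)

    truth = truth_classes(sim, test_cands)
    known = truth >= 0
    responses = res.predict(features_frame(test_cands))
    auc = float(roc_auc_score(truth[known], responses[known]))
    artifacts = known & (truth == 0)
    leakage = float(np.mean(responses[artifacts] > cfg.gam_cutoff))
    dnm_mask = known & (truth == 1)
    retention = float(np.mean(responses[dnm_mask] > cfg.gam_cutoff))
    all_resp = res.predict(features_frame(cands))
    midzone = float(np.mean((all_resp >= 0.2) & (all_resp <= 0.8)))
    return {
        "n_candidates": len(cands),
        "n_train": len(train_cands),
        "n_test": len(test_cands),
        "artifact_fraction": float(np.mean(truth_classes(sim, cands) == 0)),
        "auc": auc,
        "artifact_leakage": leakage,
        "dnm_retention": retention,
        "midzone_fraction": midzone,
    }


def phasing_accuracy(sim: SimResult, result: PipelineResult) -> Dict[str, float]:
    """Fraction of phased consensus calls matching the planted parent of origin."""
    origin = {(d.proband_id, d.chrom, d.pos): d.origin for d in sim.truth.dnms}
    twin_map: Dict[str, str] = {}
    for p, t in sim.truth.twin_pairs:
        twin_map[p] = t
        twin_map[t] = p
    n = correct = 0
    n_pat = 0
    for call in result.consensus_calls:
        if not call.phased:
            continue
        pid, chrom, pos = call.candidate_key[0], call.candidate_key[1], call.candidate_key[2]
        want = origin.get((pid, chrom, pos))
        if want is None and pid in twin_map:
            want = origin.get((twin_map[pid], chrom, pos))
        if want is None:
            continue  # phased artifact: no defined parent of origin
        n += 1
        correct += call.origin == want
        n_pat += call.origin == PATERNAL
    return {
        "n_phased_with_truth": n,
        "accuracy": correct / n if n else float("nan"),
        "paternal_fraction_estimate": n_pat / n if n else float("nan"),
    }


def twin_recovery(sim: SimResult, result: PipelineResult) -> Dict[str, float]:
    """Pooled MZ discordance vs the planted post-twinning fraction."""
    from .reports import pooled_twin_discordance

    pooled = pooled_twin_discordance(result.twin_checks)
    p = sim.config.post_twinning_fraction
    n = pooled["n_verifiable"]
    se = float(np.sqrt(p * (1 - p) / n)) if n else float("nan")
    return {
        "planted_fraction": p,
        "observed_discordance": pooled["pooled_discordance"],
        "n_verifiable": n,
        "binomial_se": se,
    }
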