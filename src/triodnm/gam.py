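"""Penalized-spline logistic classifier of DNM candidate quality.

The transmission label (consistent vs inconsistent segregation in
three-generation families) is regressed on four covariates:

    label ~ s(proband allelic balance) + s(FoxoG) + s(Trio-NPOSS) + gatk_filter

with ``s()`` a penalized cubic B-spline smooth and the GATK filter status a
linear binary term, on the logit scale.  The fitted model scores every
candidate; responses strictly above the cutoff (default 0.8) define the
high-quality DNM set.

The model/results split follows statsmodels: :class:`TransmissionGam` is
built from labelled candidates, its :meth:`~TransmissionGam.fit` returns a
:class:`TransmissionGamResults` carrying the fitted smooths, diagnostics and
prediction methods, and the results object serializes to portable JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.gam.gam_cross_validation.cross_validators import KFold


class _SeededKFold(KFold):
    """K-fold splitter with a deterministic shuffle (fit reproducibility)."""

    def __init__(self, k_folds: int, seed: int = 0):
        super().__init__(k_folds, shuffle=False)
        self._seed = seed

    def split(self, X, y=None, label=None):
        nobs = X.shape[0]
        index = np.random.default_rng(self._seed).permutation(nobs)
        folds = np.array_split(index, self.k_folds)
        for fold in folds:
            test_index = np.zeros(nobs, dtype=bool)
            test_index[fold] = True
            yield np.logical_not(test_index), test_index

from .config import RunConfig
from .datatypes import DNMCandidate
from .transmission import CONSISTENT, TransmissionLabel, foxog_metric

FEATURE_COLUMNS = ["proband_allelic_balance", "oxo_g_foxog", "trio_nposs", "gatk_filter"]
SMOOTH_COLUMNS = FEATURE_COLUMNS[:3]


@dataclass
class GamFeatures:
    proband_allelic_balance: float
    oxo_g_foxog: float
    trio_nposs: int
    gatk_filter: int

    def __post_init__(self) -> None:
        if self.gatk_filter not in (0, 1):
            raise ValueError("gatk_filter must be binary")
        for v in (self.proband_allelic_balance, self.oxo_g_foxog):
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError("fractional covariates must lie in [0, 1]")


def features_from_candidate(cand: DNMCandidate) -> GamFeatures:
    return GamFeatures(
        proband_allelic_balance=cand.proband_ab,
        oxo_g_foxog=foxog_metric(cand.site, cand.proband_ev),
        trio_nposs=cand.n_possible_outside,
        gatk_filter=int(cand.gatk_pass),
    )


def features_frame(cands: Sequence[DNMCandidate]) -> pd.DataFrame:
    rows = [features_from_candidate(c).__dict__ for c in cands]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


class SingleClassError(ValueError):
    """Training labels contain only one class; the model cannot be fitted."""


class TransmissionGam:
    """Additive logistic model of transmission consistency.

    Parameters
    ----------
    endog : array-like of {0, 1}
        1 for transmission-consistent candidates.
    exog : DataFrame
        Columns ``proband_allelic_balance``, ``oxo_g_foxog``, ``trio_nposs``,
        ``gatk_filter``.
    spline_df : int
        Basis dimension of each smooth (cubic B-splines).  A covariate with
        too few distinct values to support the basis enters linearly.
    """

    def __init__(self, endog, exog: pd.DataFrame, spline_df: int = 10):
        y = np.asarray(endog, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("endog must be binary")
        if len(np.unique(y)) < 2:
            raise SingleClassError("both consistent and inconsistent labels required")
        missing = [c for c in FEATURE_COLUMNS if c not in exog.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        if len(exog) != len(y):
            raise ValueError("endog/exog length mismatch")
        if len(y) < 50:
            warnings.warn(f"only {len(y)} labelled candidates; fit may be unstable")
        self.endog = y
        self.exog = exog.reset_index(drop=True)
        self.spline_df = spline_df
        # Smooths need enough distinct values to place knots; degenerate
        # covariates fall back to linear terms.
        self.smooth_cols = [
            c
            for c in SMOOTH_COLUMNS
            if self.exog[c].nunique() >= spline_df
        ]
        self.linear_cols = ["gatk_filter"] + [
            c for c in SMOOTH_COLUMNS if c not in self.smooth_cols
        ]

    @classmethod
    def from_candidates(
        cls,
        cands: Sequence[DNMCandidate],
        labels: Sequence[TransmissionLabel],
        spline_df: int = 10,
    ) -> "TransmissionGam":
        """Build from candidates and their transmission labels.

        Unevaluable labels are dropped; consistent maps to 1.
        """
        by_key = {lab.candidate_key: lab for lab in labels}
        keep, y = [], []
        for cand in cands:
            lab = by_key.get(cand.key)
            if lab is None or lab.label not in (CONSISTENT, "inconsistent"):
                continue
            keep.append(cand)
            y.append(1.0 if lab.label == CONSISTENT else 0.0)
        return cls(np.array(y), features_frame(keep), spline_df=spline_df)

    def _design(self) -> Tuple[np.ndarray, Optional[BSplines]]:
        x_linear = sm.add_constant(
            self.exog[self.linear_cols].to_numpy(dtype=float), has_constant="add"
        )
        smoother = None
        if self.smooth_cols:
            smoother = BSplines(
                self.exog[self.smooth_cols].to_numpy(dtype=float),
                df=[self.spline_df] * len(self.smooth_cols),
                degree=[3] * len(self.smooth_cols),
            )
        return x_linear, smoother

    def fit(
        self,
        alpha: Optional[Sequence[float]] = None,
        select_penalty: bool = True,
        penalty_grid: Sequence[float] = (0.1, 10.0, 1000.0),
    ) -> "TransmissionGamResults":
        """Fit by penalized IRLS; smoothing chosen per smooth by k-fold CV on a grid.

        ``alpha`` fixes the penalty weights and disables selection.
        """
        x_linear, smoother = self._design()
        family = sm.families.Binomial()
        if smoother is None:
            model = sm.GLM(self.endog, x_linear, family=family)
            res = model.fit()
            return TransmissionGamResults(self, res.params, None, res)
        k = len(self.smooth_cols)
        if alpha is not None:
            alphas = list(alpha)
            if len(alphas) != k:
                raise ValueError(f"need {k} penalty weights")
        else:
            alphas = [1.0] * k
        model = GLMGam(self.endog, exog=x_linear, smoother=smoother, alpha=alphas, family=family)
        if alpha is None and select_penalty:
            try:
                alphas = list(
                    model.select_penweight_kfold(
                        alphas=[list(penalty_grid)] * k,
                        cv_iterator=_SeededKFold(5),
                    )[0]
                )
            except Exception:
                try:
                    alphas = list(model.select_penweight()[0])
                except Exception:
                    alphas = [1.0] * k
            model = GLMGam(
                self.endog, exog=x_linear, smoother=smoother, alpha=alphas, family=family
            )
        # a near-separable training set can make weakly penalized IRLS
        # diverge; escalate the roughness penalty until the fit stabilizes
        res = None
        last_exc: Optional[Exception] = None
        for _ in range(4):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit()
                break
            except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
                last_exc = exc
                alphas = [max(a, 1.0) * 100.0 for a in alphas]
                model = GLMGam(
                    self.endog, exog=x_linear, smoother=smoother, alpha=alphas,
                    family=family,
                )
        if res is None:
            raise last_exc
        return TransmissionGamResults(self, np.asarray(res.params), alphas, res)


class TransmissionGamResults:
    """Fitted transmission GAM: predictions, diagnostics, serialization."""

    def __init__(
        self,
        model: TransmissionGam,
        params: np.ndarray,
        alpha: Optional[List[float]],
        sm_results=None,
    ):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.alpha = alpha
        self._sm_results = sm_results
        self.train_ranges: Dict[str, Tuple[float, float]] = {
            c: (float(model.exog[c].min()), float(model.exog[c].max()))
            for c in FEATURE_COLUMNS
        }

    # -- prediction ----------------------------------------------------------

    def _design_for(self, exog: pd.DataFrame) -> np.ndarray:
        m = self.model
        x_linear = sm.add_constant(
            exog[m.linear_cols].to_numpy(dtype=float), has_constant="add"
        )
        parts = [x_linear]
        if m.smooth_cols:
            _, smoother = m._design()
            # values beyond the training hull are clamped to the boundary
            # (constant extrapolation of each smooth); such rows are reported
            # by :meth:`extrapolated`
            x_smooth = exog[m.smooth_cols].to_numpy(dtype=float).copy()
            for j, c in enumerate(m.smooth_cols):
                lo, hi = self.train_ranges[c]
                x_smooth[:, j] = np.clip(x_smooth[:, j], lo, hi)
            basis = smoother.transform(x_smooth)
            if basis.ndim == 1:
                basis = basis[:, None]
            parts.append(basis)
        return np.column_stack(parts)

    def predict(self, exog: pd.DataFrame) -> np.ndarray:
        """Response probability per row, strictly inside (0, 1)."""
        design = self._design_for(exog)
        return expit(design @ self.params)

    def extrapolated(self, exog: pd.DataFrame) -> np.ndarray:
        """Rows with any covariate outside the training range."""
        flags = np.zeros(len(exog), dtype=bool)
        for c in FEATURE_COLUMNS:
            lo, hi = self.train_ranges[c]
            v = exog[c].to_numpy(dtype=float)
            flags |= (v < lo) | (v > hi)
        return flags

    def score_candidates(
        self,
        cands: Sequence[DNMCandidate],
        cutoff: float = 0.8,
    ) -> pd.DataFrame:
        """Score candidates; high quality means response strictly above cutoff."""
        exog = features_frame(cands)
        resp = self.predict(exog)
        return pd.DataFrame(
            {
                "proband_id": [c.proband_id for c in cands],
                "chrom": [c.site.chrom for c in cands],
                "pos": [c.site.pos for c in cands],
                "ref": [c.site.ref for c in cands],
                "alt": [c.site.alt for c in cands],
                "response": resp,
                "high_quality": resp > cutoff,
                "extrapolated": self.extrapolated(exog),
            }
        )

    def auc(self, exog: pd.DataFrame, labels) -> float:
        from sklearn.metrics import roc_auc_score

        return float(roc_auc_score(np.asarray(labels, dtype=float), self.predict(exog)))

    # -- diagnostics ---------------------------------------------------------

    def summary(self):
        if self._sm_results is not None:
            return self._sm_results.summary()
        lines = ["TransmissionGam (deserialized)"]
        lines.append(f"  smooth terms: {self.model.smooth_cols}")
        lines.append(f"  linear terms: {self.model.linear_cols}")
        lines.append(f"  penalty weights: {self.alpha}")
        lines.append(f"  n params: {len(self.params)}")
        return "\n".join(lines)

    @property
    def deviance(self) -> Optional[float]:
        if self._sm_results is None:
            return None
        return float(self._sm_results.deviance)

    # -- serialization -------------------------------------------------------

    def to_json(self, path) -> None:
        """Portable text serialization (training covariates define the basis)."""
        payload = {
            "spline_df": self.model.spline_df,
            "smooth_cols": self.model.smooth_cols,
            "linear_cols": self.model.linear_cols,
            "params": self.params.tolist(),
            "alpha": self.alpha,
            "train_exog": {
                c: self.model.exog[c].tolist() for c in FEATURE_COLUMNS
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TransmissionGamResults":
        with open(path) as fh:
            payload = json.load(fh)
        exog = pd.DataFrame(payload["train_exog"], columns=FEATURE_COLUMNS)
        n = len(exog)
        # Reconstruct a model shell with a synthetic balanced label vector:
        # only the design (training covariates + basis) matters for predict.
        y = np.zeros(n)
        y[: max(1, n // 2)] = 1.0
        model = TransmissionGam(y, exog, spline_df=payload["spline_df"])
        res = cls(model, np.asarray(payload["params"]), payload["alpha"])
        return res


def fit_transmission_gam(
    cands: Sequence[DNMCandidate],
    labels: Sequence[TransmissionLabel],
    config: Optional[RunConfig] = None,
) -> TransmissionGamResults:
    """Convenience wrapper: build from labelled candidates and fit."""
    cfg = config or RunConfig()
    model = TransmissionGam.from_candidates(cands, labels, spline_df=cfg.gam_spline_df)
    return model.fit(select_penalty=cfg.gam_select_penalty)
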