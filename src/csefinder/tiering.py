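"""Tier 1 / Tier 2 assignment.

A Tier 1 target passes every applicable check: (1) no high expression in
the normal tissue paired to any supporting tumor type, (2) low bone
marrow expression for gene-level targets (logistic model on calibration
genes; AS targets are exempt because bone-marrow data is gene-level),
and (3) low normal-tissue protein abundance relative to the bimodal
nPSM cutoff.  Any failed or missing evidence demotes to Tier 2 — the
fail-safe never promotes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture

from .curation import PASS, FAIL, NA, CheckResult
from .synthetic import PAIR_MAP


def add_npsm(proteomics: pd.DataFrame) -> pd.DataFrame:
    """Derive nPSM = psm / coding length (amino acids) per record."""
    if (proteomics["aa_length"] <= 0).any():
        raise ValueError("coding lengths must be positive")
    out = proteomics.copy()
    out["npsm"] = out["psm"] / out["aa_length"]
    return out


def paired_normal_check(
    exon_id: str,
    supporting_groups: list[str],
    ranks: pd.DataFrame,
    samples: pd.DataFrame,
    pair_map: dict[str, str] | None = None,
    high_rank: float = 0.75,
) -> CheckResult:
    """Fail iff any supporting tumor type's paired tissue is highly expressed.

    "High" is median percentile rank >= ``high_rank`` (the 3rd-quartile
    convention).  Tumor types without a paired tissue are exempt.
    """
    pair_map = PAIR_MAP if pair_map is None else pair_map
    evidence = {}
    ok = True
    for g in supporting_groups:
        tissue = pair_map.get(g)
        if tissue is None:
            continue
        cols = [s for s in samples.index[samples["group"] == tissue] if s in ranks.columns]
        if not cols:
            raise KeyError(f"pair map references unknown tissue {tissue!r}")
        med = float(np.median(ranks.loc[exon_id, cols]))
        evidence[f"{g}/{tissue}"] = round(med, 4)
        if med >= high_rank:
            ok = False
    if not evidence:
        return CheckResult(NA, {"note": "no paired tumor types"})
    return CheckResult(PASS if ok else FAIL, evidence)


@dataclass
class BMClassifier:
    """Logistic model of bone-marrow expressed-status on log2(median+1)."""

    model: LogisticRegression
    coef: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        self.coef = float(self.model.coef_[0, 0])
        self.intercept = float(self.model.intercept_[0])

    def prob_expressed(self, bm_median: float) -> float:
        x = np.log2(bm_median + 1.0)
        return float(self.model.predict_proba([[x]])[0, 1])


def fit_bm_classifier(
    calibration: pd.DataFrame,
    bm_expr: pd.Series,
    ridge_c: float = 1.0,
) -> BMClassifier:
    """Fit the bone-marrow expression model on labeled calibration genes.

    ``calibration`` has columns (gene_id, bm_expressed in {0,1});
    ``bm_expr`` maps gene_id to median bone-marrow expression.  The L2
    penalty (C=``ridge_c``) keeps fully separated calibration sets
    well-posed.
    """
    cal = calibration[calibration["gene_id"].isin(bm_expr.index)]
    y = cal["bm_expressed"].astype(int).to_numpy()
    if (y == 1).sum() < 10 or (y == 0).sum() < 10:
        raise ValueError("need >=10 positive and >=10 negative calibration genes")
    x = np.log2(bm_expr.loc[cal["gene_id"]].to_numpy(dtype=float) + 1.0).reshape(-1, 1)
    model = LogisticRegression(C=ridge_c, solver="lbfgs")
    model.fit(x, y)
    return BMClassifier(model)


def bm_low_expression(
    gene_id: str,
    bm_expr: pd.Series,
    classifier: BMClassifier,
    is_gene_level: bool = True,
) -> CheckResult:
    """Pass iff predicted expressed-probability < 0.5 (gene-level targets only)."""
    if not is_gene_level:
        return CheckResult(NA, {"note": "AS target; bone-marrow data is gene-level"})
    if gene_id not in bm_expr.index:
        return CheckResult(FAIL, {"note": "no-data"})
    p = classifier.prob_expressed(float(bm_expr[gene_id]))
    return CheckResult(PASS if p < 0.5 else FAIL, {"prob_expressed": round(p, 4)})


def bimodal_cutoff(
    npsm_values,
    random_state: int = 0,
    min_values: int = 20,
    min_ashman_d: float = 2.0,
    n_init: int = 5,
) -> tuple[float, bool]:
    """Cutoff between the two modes of log10(nPSM) for positive values.

    Fits a 2-component Gaussian mixture by EM (k-means init, best of
    ``n_init`` restarts) and returns the equal-posterior point between
    the component means.  Degeneracy is judged by Ashman's D
    (|m2-m1| / sqrt((s1^2+s2^2)/2)): a 2-component fit of a unimodal
    sample lands well below 2, a genuinely bimodal one well above.  A
    degenerate fit falls back to the distribution median; the second
    return value flags the fallback.
    """
    vals = np.asarray(npsm_values, dtype=float)
    vals = vals[vals > 0]
    if vals.size < min_values:
        raise ValueError(f"need >= {min_values} positive nPSM values")
    logv = np.log10(vals).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=n_init,
        init_params="kmeans", random_state=random_state,
    ).fit(logv)
    m1, m2 = sorted(gm.means_.ravel())
    s1, s2 = np.sqrt(gm.covariances_.ravel())
    ashman_d = abs(m2 - m1) / np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    if ashman_d < min_ashman_d:
        return float(np.median(logv)), True
    lo_comp = int(np.argmin(gm.means_.ravel()))

    def posterior_diff(x: float) -> float:
        p = gm.predict_proba([[x]])[0]
        return p[lo_comp] - p[1 - lo_comp]

    try:
        cut = brentq(posterior_diff, m1, m2)
    except ValueError:  # same sign at both means: overlapping fit
        return float(np.median(logv)), True
    return float(cut), False


def protein_abundance_flag(
    gene_id: str,
    normal_proteomics: pd.DataFrame,
    cutoff_log10: float,
) -> CheckResult:
    """High iff the gene's average exon nPSM is at or above the cutoff."""
    sub = normal_proteomics[
        (normal_proteomics["panel"] == "normal") & (normal_proteomics["gene_id"] == gene_id)
    ]
    if len(sub) == 0:
        return CheckResult(FAIL, {"note": "no-data"})
    avg = float(add_npsm(sub)["npsm"].mean())
    high = np.log10(avg) >= cutoff_log10 if avg > 0 else False
    return CheckResult(
        FAIL if high else PASS,
        {"avg_npsm_log10": round(float(np.log10(avg)), 4) if avg > 0 else None},
    )


@dataclass
class TierAssignment:
    target: str
    tier: int
    failed_checks: list[str]
    evidence: dict[str, object]


def assign_tier(target: str, checks: dict[str, CheckResult]) -> TierAssignment:
    """Tier 1 iff all applicable checks pass; evidence retained per check."""
    failed = sorted(name for name, res in checks.items() if res.status == FAIL)
    return TierAssignment(
        target=target,
        tier=1 if not failed else 2,
        failed_checks=failed,
        evidence={name: res.evidence for name, res in checks.items()},
    )
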