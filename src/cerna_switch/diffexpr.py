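"""Differential expression with tiered significance thresholds.

The test is a deliberately simple, fully specified negative-binomial Wald
test: median-of-ratios size factors, per-gene method-of-moments dispersion
(floored at 1e-8), a delta-method standard error on the log2 ratio of
normalized group means (pseudocount 0.5), and Benjamini-Hochberg FDR.
It is not a DESeq2 reimplementation — no dispersion shrinkage, no Cox-Reid
adjustment — but every step is deterministic and reproducible.

Three significance tiers are applied downstream of the test:

=============  =====================================================
screening      |FC| >= 2 and FDR <= 0.05
stringent      FDR <= 0.01 and |log2FC| >= 2 and max mean FPKM > 1
ceRNA          |log2FC| > 2.5 (lncRNA) or > 1.5 (miRNA/mRNA), FDR < 0.01
=============  =====================================================

Boundary semantics follow the printed operators of each tier verbatim:
the screening/stringent tiers are inclusive (>=, <=), the ceRNA tier is
strict (>, <). Genes sitting exactly on the screening FDR boundary are
flagged (``fdr_at_screening_boundary``) so that either a strict or an
inclusive reading of that cutoff can be recovered from the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

__all__ = [
    "TierThresholds",
    "AssociationTable",
    "size_factors",
    "test_de",
    "classify",
    "association",
    "class_direction_association",
]

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5
LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class TierThresholds:
    """All tier cutoffs, defaulting to the study's values."""

    screening_abs_fc: float = 2.0
    screening_max_fdr: float = 0.05
    stringent_max_fdr: float = 0.01
    stringent_abs_log2fc: float = 2.0
    stringent_min_fpkm: float = 1.0
    cerna_lnc_abs_log2fc: float = 2.5
    cerna_small_abs_log2fc: float = 1.5
    cerna_max_fdr: float = 0.01

    def validate(self) -> None:
        for name in ("screening_max_fdr", "stringent_max_fdr", "cerna_max_fdr"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "screening_abs_fc",
            "stringent_abs_log2fc",
            "stringent_min_fpkm",
            "cerna_lnc_abs_log2fc",
            "cerna_small_abs_log2fc",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    For each gene positive in every sample, the ratio of each sample's count
    to the gene's geometric mean is formed; a sample's factor is the median
    of its ratios.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in all samples")
    sub = mat[positive]
    log_geo_mean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo_mean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def test_de(
    counts: ExpressionMatrix,
    control: str,
    treated: str,
) -> pd.DataFrame:
    """Per-gene NB Wald test of *treated* over *control*.

    Returns a DataFrame indexed by gene id with ``base_mean``, ``log2fc``,
    ``dispersion``, ``p_value`` and ``fdr`` columns. Requires two conditions
    with at least two replicates each.
    """
    if counts.unit != "counts":
        raise ValueError("test_de requires a counts matrix")
    cond = counts.sample_condition
    for label in (control, treated):
        n = sum(cond[s] == label for s in counts.samples)
        if n < 2:
            raise ValueError(f"condition {label!r} has {n} replicates; need >= 2")

    sf = size_factors(counts.values)
    norm = counts.values.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    idx_c = [i for i, s in enumerate(counts.samples) if cond[s] == control]
    idx_t = [i for i, s in enumerate(counts.samples) if cond[s] == treated]
    xc, xt = norm[:, idx_c], norm[:, idx_t]
    n_c, n_t = xc.shape[1], xt.shape[1]

    m_c, m_t = xc.mean(axis=1), xt.mean(axis=1)
    v_c, v_t = xc.var(axis=1, ddof=1), xt.var(axis=1, ddof=1)
    base_mean = norm.mean(axis=1)
    log2fc = np.log2((m_t + PSEUDOCOUNT) / (m_c + PSEUDOCOUNT))

    # pooled within-group method-of-moments NB dispersion:
    # Var = mu + alpha * mu^2  =>  alpha = (s2 - mu) / mu^2
    s2 = ((n_c - 1) * v_c + (n_t - 1) * v_t) / (n_c + n_t - 2)
    mu = (m_c + m_t) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu > 0, (s2 - mu) / np.square(mu), DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    # delta-method variance of log2(mean + pseudocount) per group
    var_mean_c = (m_c + alpha * np.square(m_c)) / n_c
    var_mean_t = (m_t + alpha * np.square(m_t)) / n_t
    var_log2_c = var_mean_c / np.square((m_c + PSEUDOCOUNT) * LN2)
    var_log2_t = var_mean_t / np.square((m_t + PSEUDOCOUNT) * LN2)
    se = np.sqrt(var_log2_c + var_log2_t)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene_class": counts.gene_class[counts.values.index].to_numpy(),
            "base_mean": base_mean,
            "log2fc": log2fc,
            "dispersion": alpha,
            "p_value": p,
            "fdr": np.maximum(fdr, p),
        },
        index=counts.values.index.rename("gene_id"),
    )


def classify(
    de: pd.DataFrame,
    fpkm: ExpressionMatrix,
    control: str,
    treated: str,
    thresholds: TierThresholds = TierThresholds(),
) -> pd.DataFrame:
    """Attach mean FPKM, direction and boolean tier flags to DE results.

    The FPKM quantifiability criterion uses the larger of the two
    per-condition mean FPKMs. ``direction`` is ``up``/``down`` by the sign
    of log2FC for genes carrying at least one tier flag and ``ns``
    otherwise.
    """
    thresholds.validate()
    missing = set(de.index) - set(fpkm.values.index)
    if missing:
        raise ValueError(f"genes missing from FPKM: {sorted(missing)[:10]}")
    out = de.copy()
    f = fpkm.values.loc[out.index]
    mean_c = f[fpkm.samples_of(control)].mean(axis=1)
    mean_t = f[fpkm.samples_of(treated)].mean(axis=1)
    out["mean_fpkm_control"] = mean_c
    out["mean_fpkm_treated"] = mean_t
    max_fpkm = np.maximum(mean_c, mean_t)

    abs_lfc = out["log2fc"].abs()
    t = thresholds
    out["screening"] = (abs_lfc >= np.log2(t.screening_abs_fc)) & (
        out["fdr"] <= t.screening_max_fdr
    )
    out["fdr_at_screening_boundary"] = out["fdr"] == t.screening_max_fdr
    out["stringent"] = (
        (out["fdr"] <= t.stringent_max_fdr)
        & (abs_lfc >= t.stringent_abs_log2fc)
        & (max_fpkm > t.stringent_min_fpkm)
    )
    is_lnc = out["gene_class"] == "lncRNA"
    out["cerna_lnc"] = (
        is_lnc & (abs_lfc > t.cerna_lnc_abs_log2fc) & (out["fdr"] < t.cerna_max_fdr)
    )
    out["cerna_small"] = (
        ~is_lnc & (abs_lfc > t.cerna_small_abs_log2fc) & (out["fdr"] < t.cerna_max_fdr)
    )
    flagged = out[["screening", "stringent", "cerna_lnc", "cerna_small"]].any(axis=1)
    out["direction"] = np.where(
        flagged, np.where(out["log2fc"] > 0, "up", "down"), "ns"
    )
    return out


@dataclass
class AssociationTable:
    """Down/up counts per RNA class with the independence chi-square.

    ``table`` has one row per class with columns ``down``, ``up``,
    ``down_pct``, ``up_pct`` and ``total``. The statistic is the Pearson
    chi-square without continuity correction; for 2x2 tables Fisher's exact
    p-value is reported as well.
    """

    table: pd.DataFrame
    chi_square: float
    dof: int
    p_value: float
    fisher_p: float | None = None


def class_direction_association(counts: pd.DataFrame) -> AssociationTable:
    """Association statistics for a classes x (down, up) count table."""
    obs = counts[["down", "up"]].to_numpy(dtype=float)
    if (obs < 0).any():
        raise ValueError("negative cell counts")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    fisher_p = None
    if obs.shape == (2, 2):
        fisher_p = float(stats.fisher_exact(obs)[1])
    table = counts[["down", "up"]].copy()
    totals = table.sum(axis=1)
    table["down_pct"] = (table["down"] / totals * 100).round(1)
    table["up_pct"] = (table["up"] / totals * 100).round(1)
    table["total"] = totals
    return AssociationTable(table, float(chi2), int(dof), float(p), fisher_p)


def association(
    classified: pd.DataFrame,
    tier: str,
    class_groups: dict[str, list[str]] | None = None,
) -> AssociationTable:
    """Class x direction association among genes flagged in *tier*.

    ``class_groups`` maps display labels to lists of RNA classes; the
    default keeps mRNA/lncRNA/miRNA separate. Classes with no flagged gene
    are dropped with a warning.
    """
    if tier not in ("screening", "stringent", "cerna"):
        raise ValueError(f"unknown tier {tier!r}")
    if class_groups is None:
        class_groups = {"mRNA": ["mRNA"], "lncRNA": ["lncRNA"], "miRNA": ["miRNA"]}
    if tier == "cerna":
        flagged = classified[classified[["cerna_lnc", "cerna_small"]].any(axis=1)]
    else:
        flagged = classified[classified[tier]]
    rows = {}
    for label, members in class_groups.items():
        sub = flagged[flagged["gene_class"].isin(members)]
        if sub.empty:
            warnings.warn(f"class {label!r} has no genes flagged in tier {tier!r}")
            continue
        rows[label] = {
            "down": int((sub["direction"] == "down").sum()),
            "up": int((sub["direction"] == "up").sum()),
        }
    if len(rows) < 2:
        raise ValueError("need at least two classes with flagged genes")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "rna_class"
    return class_direction_association(table)
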