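"""Per-condition significance and missing-value-tolerant meta-analysis.

Each kinase-dead-vs-WT condition contributes a two-tailed p-value per
peptide, computed as twice its significance B value (the robust,
percentile-scaled outlier statistic for a log ratio relative to the
experiment's ratio distribution).  Global significance combines the
available per-condition p-values with an extension of Fisher's combined
probability test: X = -2 sum(ln p_i) over the m non-missing entries is
referred to a chi-square distribution with 2m degrees of freedom, so
incomplete peptides are tested rather than discarded.  An adaptively
weighted (AW) statistic over all nonzero binary weight vectors, calibrated
against a Monte-Carlo null, serves as a complete-measurement cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_model import KINASES, RatioMatrix, map_peptides_to_proteins
from .errors import ValidationError

#: Smallest p admitted to the log transform; smaller values are floored
#: (with a warning) to keep -2 ln p finite.
P_FLOOR = 1e-300

# Robust one-sigma percentiles: Phi(1) and Phi(-1) as percentages.
_P_HI = 84.13
_P_LO = 15.87


# ---------------------------------------------------------------------------
# Significance B (outlier statistic for a single ratio)

def significance_b(log2_ratios: np.ndarray, target: float) -> float:
    """Two-tailed outlier p-value of one log2 ratio within a distribution.

    The empirical ratio distribution is centered at its median; deviations
    are scaled by the side-appropriate robust sigma (84.13th percentile
    minus median on the right, median minus 15.87th percentile on the
    left), and the standardized deviation is referred to a standard normal.

    Requires at least 20 finite values to estimate the distribution.
    """
    x = np.asarray(log2_ratios, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValidationError(
            f"need >= 20 finite log2 ratios to estimate the distribution, got {x.size}"
        )
    med = np.median(x)
    right = np.percentile(x, _P_HI) - med
    left = med - np.percentile(x, _P_LO)
    d = target - med
    scale = right if d >= 0 else left
    if scale <= 0:
        side = "right" if d >= 0 else "left"
        raise ValidationError(f"degenerate ratio distribution: zero {side} scale")
    z = d / scale
    return float(2.0 * stats.norm.sf(abs(z)))


def significance_b_batch(log2_ratios: np.ndarray) -> np.ndarray:
    """Vectorized significance B of every value against the full sample."""
    x = np.asarray(log2_ratios, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 20:
        raise ValidationError(
            f"need >= 20 finite log2 ratios to estimate the distribution, got {finite.size}"
        )
    med = np.median(finite)
    right = np.percentile(finite, _P_HI) - med
    left = med - np.percentile(finite, _P_LO)
    if right <= 0 or left <= 0:
        side = "right" if right <= 0 else "left"
        raise ValidationError(f"degenerate ratio distribution: zero {side} scale")
    d = x - med
    z = np.where(d >= 0, d / right, d / left)
    out = 2.0 * stats.norm.sf(np.abs(z))
    out[~np.isfinite(x)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Extended Fisher combination

@dataclass(frozen=True)
class FisherResult:
    statistic: float
    dof: int
    p_value: float
    m_available: int


def combine_fisher_extended(per_condition_p) -> FisherResult:
    """Fisher's combined probability test over the non-missing entries.

    X = -2 sum(ln p_i) over the m available p-values follows chi-square
    with 2m degrees of freedom under the null; with all 8 entries present
    this is the classical Fisher statistic.  With every entry missing the
    result is an NaN sentinel (m_available == 0), not an exception.
    """
    p = np.asarray(
        [np.nan if v is None else float(v) for v in per_condition_p], dtype=float
    )
    present = ~np.isnan(p)
    vals = p[present]
    if np.any((vals < 0) | (vals > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = int(present.sum())
    if m == 0:
        return FisherResult(np.nan, 0, np.nan, 0)
    if np.any(vals == 0):
        warnings.warn(
            f"p-value of 0 floored to {P_FLOOR} before log transform",
            RuntimeWarning,
            stacklevel=2,
        )
        vals = np.maximum(vals, P_FLOOR)
    x = float(-2.0 * np.sum(np.log(vals)))
    dof = 2 * m
    return FisherResult(x, dof, float(stats.chi2.sf(x, dof)), m)


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must be finite and lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Adaptively weighted statistic

_N_CONDITIONS = len(KINASES)
# All 255 nonzero binary weight vectors over the 8 conditions.
_WEIGHT_MASKS = np.array(
    [[(w >> i) & 1 for i in range(_N_CONDITIONS)] for w in range(1, 2 ** _N_CONDITIONS)],
    dtype=bool,
)
_WEIGHT_SIZES = _WEIGHT_MASKS.sum(axis=1)


def _min_weighted_p(neg2logp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimum weighted-combination p over all 255 weight vectors.

    ``neg2logp`` has shape (n, 8); returns (min p per row, argmin index).
    """
    stats_all = neg2logp @ _WEIGHT_MASKS.T  # (n, 255)
    pvals = np.empty_like(stats_all)
    for size in range(1, _N_CONDITIONS + 1):
        cols = _WEIGHT_SIZES == size
        pvals[:, cols] = stats.chi2.sf(stats_all[:, cols], 2 * size)
    idx = np.argmin(pvals, axis=1)
    return pvals[np.arange(len(pvals)), idx], idx


@dataclass(frozen=True)
class AwResult:
    best_weight_vector: tuple[int, ...]
    aw_statistic: float
    calibrated_p: float
    n_null_draws: int
    seed: int


def aw_null_minima(n_null: int, seed: int) -> np.ndarray:
    """Null distribution of the AW statistic: minimum weighted p over 255
    weight vectors for n_null draws of 8 independent uniform p-values."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=(n_null, _N_CONDITIONS))
    mins, _ = _min_weighted_p(-2.0 * np.log(u))
    return mins


def aw_statistic(
    per_condition_p, n_null: int = 10_000, seed: int = 0,
    null_minima: np.ndarray | None = None,
) -> AwResult:
    """Adaptively weighted combination over a complete 8-vector of p-values.

    For every nonzero binary weight vector w the weighted statistic
    sum(w_i * -2 ln p_i) is referred to chi-square(2 |w|); the AW statistic
    is the minimum such p-value.  Because the minimum over 255 correlated
    tests is not itself a p-value, it is calibrated against a Monte-Carlo
    null of uniform 8-vectors with add-one smoothing.

    Missing values are not allowed (complete-measurement method).
    """
    p = np.asarray(per_condition_p, dtype=float)
    if p.shape != (_N_CONDITIONS,):
        raise ValidationError(f"expected a complete vector of {_N_CONDITIONS} p-values")
    if np.any(~np.isfinite(p)):
        raise ValidationError("missing values not allowed in the AW statistic")
    if np.any((p <= 0) | (p > 1)):
        p = np.clip(p, P_FLOOR, 1.0)
    if null_minima is None:
        if n_null < 1000:
            raise ValidationError("n_null must be >= 1000")
        null_minima = aw_null_minima(n_null, seed)
    obs_min, idx = _min_weighted_p(-2.0 * np.log(p)[None, :])
    calibrated = (np.sum(null_minima <= obs_min[0]) + 1.0) / (len(null_minima) + 1.0)
    return AwResult(
        best_weight_vector=tuple(int(b) for b in _WEIGHT_MASKS[idx[0]]),
        aw_statistic=float(obs_min[0]),
        calibrated_p=float(calibrated),
        n_null_draws=len(null_minima),
        seed=seed,
    )


def aw_screen(
    p_frame: pd.DataFrame, n_null: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """AW statistic for many complete peptides, sharing one null sample."""
    null_minima = aw_null_minima(n_null, seed)
    rows = {}
    for key, row in p_frame.iterrows():
        res = aw_statistic(row.to_numpy(), null_minima=null_minima, seed=seed)
        rows[key] = {
            "aw_statistic": res.aw_statistic,
            "aw_calibrated_p": res.calibrated_p,
            "best_weights": "".join(str(b) for b in res.best_weight_vector),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Peptide-level meta-analysis and selection rules

def meta_analyze(
    matrix: RatioMatrix, alpha: float = 0.05, min_sig_conditions: int = 4,
    sig_b_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-peptide meta-analysis table over the replicate-collapsed matrix.

    Per-condition two-tailed p-values are twice the significance B value,
    capped at 1.  The combined p-value uses the missing-value-tolerant
    Fisher extension; q-values are BH over every peptide with a defined
    combined p (complete and incomplete pooled).  A peptide is globally
    significant iff combined p < alpha, q < alpha, and significance B <
    sig_b_threshold in at least ``min_sig_conditions`` of the 8 conditions;
    high confidence additionally requires complete measurements.
    """
    sigb = matrix.significance_b
    pcond = np.minimum(1.0, 2.0 * sigb)
    pcond = pcond.where(~matrix.missing_mask)

    records = []
    for key in matrix.ratio.index:
        fr = combine_fisher_extended(pcond.loc[key].to_numpy())
        records.append(
            {
                "modified_sequence": key,
                "m_available": fr.m_available,
                "fisher_statistic": fr.statistic,
                "dof": fr.dof,
                "combined_p": fr.p_value,
            }
        )
    meta = pd.DataFrame(records).set_index("modified_sequence")
    meta["n_significant_conditions"] = (
        (sigb < sig_b_threshold) & ~matrix.missing_mask
    ).sum(axis=1)

    meta["q_value"] = np.nan
    defined = meta["combined_p"].notna()
    if defined.any():
        meta.loc[defined, "q_value"] = bh_qvalues(meta.loc[defined, "combined_p"])

    meta = select_globally_significant(meta, alpha, min_sig_conditions)
    mapping = map_peptides_to_proteins(matrix.peptides)
    meta["proteins"] = [";".join(sorted(mapping[k])) for k in meta.index]
    return meta


def select_globally_significant(
    meta: pd.DataFrame, alpha: float = 0.05, min_sig_conditions: int = 4
) -> pd.DataFrame:
    """Apply the three-part global-significance rule and the completeness flag."""
    meta = meta.copy()
    meta["globally_significant"] = (
        (meta["combined_p"] < alpha)
        & (meta["q_value"] < alpha)
        & (meta["n_significant_conditions"] >= min_sig_conditions)
    ).fillna(False)
    meta["high_confidence"] = meta["globally_significant"] & (
        meta["m_available"] == len(KINASES)
    )
    return meta


def select_differential_per_mutant(
    matrix: RatioMatrix, threshold: float = 0.05
) -> pd.DataFrame:
    """Cells significant in an individual KD-vs-WT experiment (sigB < threshold)."""
    mapping = map_peptides_to_proteins(matrix.peptides)
    rows = []
    sig = (matrix.significance_b < threshold) & ~matrix.missing_mask
    for key in matrix.ratio.index:
        for kinase in KINASES:
            if sig.at[key, kinase]:
                ratio = matrix.ratio.at[key, kinase]
                rows.append(
                    {
                        "kinase": kinase,
                        "modified_sequence": key,
                        "proteins": ";".join(sorted(mapping[key])),
                        "direction": "up" if ratio > 1 else "down",
                        "significance_b": matrix.significance_b.at[key, kinase],
                        "ratio": ratio,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "kinase", "modified_sequence", "proteins",
            "direction", "significance_b", "ratio",
        ],
    )


def build_regulation_pairs(differential: pd.DataFrame) -> pd.DataFrame:
    """Kinase -> phosphopeptide regulation edges (one edge per significant cell,
    exploded over the peptide's parent proteins)."""
    if differential.empty:
        return pd.DataFrame(
            columns=[
                "kinase", "target_protein", "modified_sequence",
                "direction", "significance_b",
            ]
        )
    df = differential.copy()
    df["target_protein"] = df["proteins"].str.split(";")
    df = df.explode("target_protein")
    return df[
        ["kinase", "target_protein", "modified_sequence", "direction", "significance_b"]
    ].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Generic gene-set enrichment plumbing

def read_gmt(path) -> dict[str, frozenset[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return sets


def hypergeometric_enrichment(
    cluster: set, annotation: dict[str, frozenset[str]], background: set
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term, BH-corrected.

    ``cluster`` must be a subset of ``background``; terms are intersected
    with the background before testing.
    """
    cluster = set(cluster)
    background = set(background)
    if not cluster <= background:
        raise ValidationError("cluster must be a subset of the background")
    n_bg, n_cl = len(background), len(cluster)
    rows = []
    for term, members in annotation.items():
        in_bg = members & background
        overlap = len(in_bg & cluster)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(in_bg), n_cl))
        rows.append(
            {"term": term, "overlap": overlap, "term_size": len(in_bg), "p_value": p}
        )
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p_value"])
    if not out.empty:
        out["q_value"] = bh_qvalues(out["p_value"])
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out
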