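"""Ground-truthed synthetic SILAC kinase-dead phosphoproteomics datasets.

The generator emulates the statistical structure the pipeline assumes:
8 kinase-dead mutant conditions x 2-3 replicates of mutant/WT log2 ratios;
log-normal measurement noise whose MaxQuant-style "variability" lands
mostly under 20; planted co-responding peptide clusters plus scattered
null peptides; planted kinase -> target causal effects with intervention
semantics (the kinase's own peptide is set exogenously in its own
kinase-dead condition); and two-layer missingness — whole-triplex blocks
dropped jointly for both mutant channels of a run, then cellwise MCAR —
reproducing the triplex-linked identification of SILAC experiments.

It does not emulate raw spectra, intensity-dependent (MNAR) missingness,
or retention-time structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import KINASES
from .errors import ValidationError
from .meta_analysis import significance_b_batch

#: Triplex design: each run carries the WT (light) plus two mutant samples.
TRIPLEX_PAIRS: tuple[tuple[str, str], ...] = (
    ("KSP1", "KSS1"), ("SKS1", "STE20"), ("SNF1", "TPK2"), ("ELM1", "FUS3"),
)

#: Default measurement noise, log2 units.  At sigma = 0.25 the simulated
#: ln-ratio "variability" (sd of log ratios x 100) sits mostly below 20.
DEFAULT_NOISE_SD = 0.25
DEFAULT_TRIPLEX_BLOCK_RATE = 0.2
DEFAULT_MCAR_RATE = 0.05

STATE_UNDER, STATE_BASELINE, STATE_OVER = 0, 1, 2

_ALPHABET = "ACDEFGHIKLMNPQRTVWY"  # no S; the phosphosite supplies it


@dataclass(frozen=True)
class CausalEdge:
    source: str            # protein (one of the mutated kinases)
    target: str            # protein
    sign: str              # "+" activating, "-" inhibitory
    effect: float          # magnitude in log2 units

    def __post_init__(self) -> None:
        if self.sign not in ("+", "-"):
            raise ValidationError("causal edge sign must be '+' or '-'")
        if self.effect <= 0:
            raise ValidationError("causal effect size must be positive")


@dataclass
class SyntheticTruth:
    """Planted structure of a generated dataset.

    Clusters are disjoint peptide index sets sharing a mean log2 response
    vector; ``scattered`` indexes pure-noise peptides explicitly counted as
    unclusterable; causal edges plant kinase -> target effects; the
    intervention map sends each condition to its intervened kinase.
    """

    seed: int
    planted_clusters: list[list[int]] = field(default_factory=list)
    cluster_means: list[np.ndarray] = field(default_factory=list)
    scattered: list[int] = field(default_factory=list)
    causal_edges: list[CausalEdge] = field(default_factory=list)
    intervention_map: dict[str, str] = field(
        default_factory=lambda: {k: k for k in KINASES}
    )
    triplex_block_rate: float = DEFAULT_TRIPLEX_BLOCK_RATE
    mcar_rate: float = DEFAULT_MCAR_RATE
    #: peptide index -> protein name overrides (causal sources/targets).
    peptide_proteins: dict[int, str] = field(default_factory=dict)
    #: source protein -> mean log2 profile over the 8 conditions.
    causal_profiles: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for cl in self.planted_clusters:
            if seen & set(cl):
                raise ValidationError("planted clusters must be pairwise disjoint")
            seen |= set(cl)
        if seen & set(self.scattered):
            raise ValidationError("scattered set must be disjoint from clusters")
        if len(self.planted_clusters) != len(self.cluster_means):
            raise ValidationError("one mean vector per planted cluster required")
        if set(self.intervention_map) != set(KINASES):
            raise ValidationError("every condition must map to an intervened kinase")
        for rate in (self.triplex_block_rate, self.mcar_rate):
            if not 0.0 <= rate < 1.0:
                raise ValidationError("missingness rates must lie in [0, 1)")


def _sequence_for(index: int) -> str:
    """Deterministic synthetic modified sequence for a peptide index."""
    letters = []
    i = index
    for _ in range(4):
        letters.append(_ALPHABET[i % len(_ALPHABET)])
        i //= len(_ALPHABET)
    return "_" + "".join(letters) + "S(ph)GR_"


def _protein_for(truth: SyntheticTruth, index: int) -> str:
    return truth.peptide_proteins.get(index, f"P{index:04d}")


def _mean_matrix(truth: SyntheticTruth, n_peptides: int) -> np.ndarray:
    """Planted mean log2 response per (peptide, condition)."""
    mean = np.zeros((n_peptides, len(KINASES)))
    for members, mu in zip(truth.planted_clusters, truth.cluster_means):
        mean[list(members)] = np.asarray(mu, dtype=float)

    # Causal structure: each source kinase has a log2 activity profile over
    # conditions (strongly negative in its own KD — the intervention); each
    # target mirrors it, scaled by the edge effect and flipped for
    # inhibitory edges.
    kinase_col = {k: j for j, k in enumerate(KINASES)}
    protein_rows: dict[str, list[int]] = {}
    for idx, prot in truth.peptide_proteins.items():
        protein_rows.setdefault(prot, []).append(idx)
    for edge in truth.causal_edges:
        profile = truth.causal_profiles.get(edge.source)
        if profile is None:
            profile = np.zeros(len(KINASES))
            profile[kinase_col[truth.intervention_map.get(edge.source, edge.source)]] = -2.0
        s = 1.0 if edge.sign == "+" else -1.0
        for row in protein_rows.get(edge.source, []):
            mean[row] = profile
        for row in protein_rows.get(edge.target, []):
            mean[row] = s * (edge.effect / 2.0) * profile
    return mean


def generate_dataset(
    truth: SyntheticTruth,
    n_peptides: int,
    n_replicates: int = 2,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a long-form quantification table with known ground truth.

    Per (peptide, condition, replicate): log2 ratio = planted mean +
    Normal(0, noise_sd).  Missingness is applied in two layers — whole
    triplex blocks dropped with probability ``triplex_block_rate`` (removing
    the peptide from both mutant channels of that run), then cellwise MCAR.
    Significance B columns are computed from the generated log2 ratio
    distribution of each (kinase, replicate) experiment.  Deterministic
    under the truth's seed.
    """
    planted = {i for cl in truth.planted_clusters for i in cl}
    planted |= set(truth.scattered) | set(truth.peptide_proteins)
    if planted and max(planted) >= n_peptides:
        raise ValidationError(
            f"n_peptides={n_peptides} too small for planted indices up to {max(planted)}"
        )
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be positive")
    if n_replicates < 1:
        raise ValidationError("need at least one replicate")

    rng = np.random.default_rng(truth.seed)
    mean = _mean_matrix(truth, n_peptides)
    kinase_col = {k: j for j, k in enumerate(KINASES)}

    rows: list[dict] = []
    for rep in range(1, n_replicates + 1):
        # layer 1: triplex block dropout, linked across the two mutant
        # channels of a run
        observed = np.ones((n_peptides, len(KINASES)), dtype=bool)
        for t, pair in enumerate(TRIPLEX_PAIRS):
            block = rng.uniform(size=n_peptides) < truth.triplex_block_rate
            for kinase in pair:
                observed[block, kinase_col[kinase]] = False
        # layer 2: cellwise MCAR
        observed &= rng.uniform(size=observed.shape) >= truth.mcar_rate

        log2 = mean + rng.normal(0.0, noise_sd, size=mean.shape)
        # MaxQuant-style variability: sd of the scan-level natural-log
        # ratios x 100, emulated with 3 scan draws per reported ratio
        scans = rng.normal(0.0, noise_sd, size=(n_peptides, len(KINASES), 3))
        variability = np.std(scans * np.log(2.0), axis=2, ddof=1) * 100.0

        for t, pair in enumerate(TRIPLEX_PAIRS):
            run_id = f"rep{rep}_triplex{t + 1}"
            for channel, kinase in zip(("medium", "heavy"), pair):
                j = kinase_col[kinase]
                obs_rows = np.flatnonzero(observed[:, j])
                if obs_rows.size == 0:
                    continue
                vals = log2[obs_rows, j]
                sigb = (
                    significance_b_batch(vals) if vals.size >= 20
                    else np.full(vals.size, np.nan)
                )
                for r, v, sb, var in zip(
                    obs_rows, vals, sigb, variability[obs_rows, j]
                ):
                    rows.append(
                        {
                            "modified_sequence": _sequence_for(int(r)),
                            "proteins": _protein_for(truth, int(r)),
                            "kinase": kinase,
                            "ratio": float(2.0 ** v),
                            "significance_b": float(sb) if np.isfinite(sb) else np.nan,
                            "variability": float(var),
                            "replicate": rep,
                            "triplex_run": run_id,
                        }
                    )
    records = pd.DataFrame(
        rows,
        columns=[
            "modified_sequence", "proteins", "kinase", "ratio",
            "significance_b", "variability", "replicate", "triplex_run",
        ],
    )
    return records, truth


# ---------------------------------------------------------------------------
# Truth constructors

def _distinct_patterns(
    rng: np.random.Generator, n: int, n_active: int | None = None,
    min_hamming: int = 3,
) -> list[np.ndarray]:
    """Distinct +-1 (optionally sparse) response patterns over 8 conditions."""
    patterns: list[np.ndarray] = []
    while len(patterns) < n:
        pat = rng.choice([-1.0, 1.0], size=len(KINASES))
        if n_active is not None:
            off = rng.choice(len(KINASES), size=len(KINASES) - n_active, replace=False)
            pat[off] = 0.0
        if all(np.sum(pat != q) >= min_hamming for q in patterns):
            patterns.append(pat)
    return patterns


def make_clustered_truth(
    seed: int,
    n_clusters: int = 2,
    cluster_size: int = 20,
    n_scattered: int = 50,
    effect: float = 1.0,
    triplex_block_rate: float = 0.0,
    mcar_rate: float = 0.0,
) -> SyntheticTruth:
    """Reference clustering scenario: dense +-effect blocks plus nulls."""
    rng = np.random.default_rng(seed)
    patterns = _distinct_patterns(rng, n_clusters)
    clusters, means = [], []
    idx = 0
    for pat in patterns:
        clusters.append(list(range(idx, idx + cluster_size)))
        means.append(effect * pat)
        idx += cluster_size
    scattered = list(range(idx, idx + n_scattered))
    return SyntheticTruth(
        seed=seed,
        planted_clusters=clusters,
        cluster_means=means,
        scattered=scattered,
        triplex_block_rate=triplex_block_rate,
        mcar_rate=mcar_rate,
    )


def make_reference_truth(
    seed: int,
    n_peptides: int = 1000,
    n_clusters: int = 6,
    cluster_size: int = 15,
    effect: float = 1.5,
    causal_effect: float = 2.0,
) -> SyntheticTruth:
    """Full-pipeline reference scenario.

    Plants: one peptide per mutated kinase (intervened in its own KD);
    four kinase -> target causal edges with sign-mirrored profiles; sparse
    cluster response patterns (4 active conditions each); the bulk of
    peptides are null.
    """
    rng = np.random.default_rng(seed)
    peptide_proteins: dict[int, str] = {}
    idx = 0
    for kinase in KINASES:
        peptide_proteins[idx] = kinase
        idx += 1
    edges = []
    kinase_col = {k: j for j, k in enumerate(KINASES)}
    causal_profiles: dict[str, np.ndarray] = {}
    for i, (source, sign) in enumerate(
        [("SNF1", "-"), ("TPK2", "+"), ("STE20", "-"), ("FUS3", "+")]
    ):
        target = f"TGT{i + 1}"
        peptide_proteins[idx] = target
        idx += 1
        profile = np.zeros(len(KINASES))
        profile[kinase_col[source]] = -2.0
        others = rng.choice(
            [j for j in range(len(KINASES)) if j != kinase_col[source]],
            size=3, replace=False,
        )
        profile[others] = rng.choice([-1.0, 1.0], size=3)
        causal_profiles[source] = profile
        edges.append(CausalEdge(source=source, target=target, sign=sign,
                                effect=causal_effect))

    patterns = _distinct_patterns(rng, n_clusters, n_active=4)
    clusters, means = [], []
    for pat in patterns:
        clusters.append(list(range(idx, idx + cluster_size)))
        means.append(effect * pat)
        idx += cluster_size
    if idx > n_peptides:
        raise ValidationError("n_peptides too small for the reference truth")
    return SyntheticTruth(
        seed=seed,
        planted_clusters=clusters,
        cluster_means=means,
        scattered=list(range(idx, n_peptides)),
        causal_edges=edges,
        peptide_proteins=peptide_proteins,
        causal_profiles=causal_profiles,
    )


def simulate_study(
    seed: int,
    n_peptides: int = 1000,
    n_replicates: int = 2,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the reference interventional study (records + truth)."""
    truth = make_reference_truth(seed, n_peptides=n_peptides)
    return generate_dataset(
        truth, n_peptides=n_peptides, n_replicates=n_replicates, noise_sd=noise_sd
    )


# ---------------------------------------------------------------------------
# Discrete causal test cases

def generate_causal_cases(
    edge: CausalEdge,
    n_conditions: int = 8,
    leak: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Discrete three-state cases for one causal edge, with one intervention.

    Case 0 is the source kinase's own kinase-dead condition: the source
    state is set exogenously to under-phosphorylation and flagged as
    intervened.  In every other case the source state is drawn uniformly.
    The target follows the source with probability 1 - leak (equal states
    for an activating edge, mirrored under/over for an inhibitory one),
    otherwise it takes a uniform state.
    """
    if not 0.0 <= leak < 0.5:
        raise ValidationError("leak must lie in [0, 0.5)")
    if n_conditions < 1:
        raise ValidationError("need at least one case")
    rng = np.random.default_rng(seed)
    source = rng.integers(0, 3, size=n_conditions)
    source[0] = STATE_UNDER
    intervened = np.zeros(n_conditions, dtype=bool)
    intervened[0] = True
    follows = rng.uniform(size=n_conditions) >= leak
    coupled = source if edge.sign == "+" else (2 - source)
    target = np.where(follows, coupled, rng.integers(0, 3, size=n_conditions))
    cases = pd.DataFrame({"source_state": source, "target_state": target})
    return cases, intervened
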