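"""Pairwise causal Bayesian network scoring with interventional data.

Replicate-collapsed ratios are discretized into three states on the
2-fold criterion (ratio < 0.5 under-phosphorylation, ratio > 2
over-phosphorylation, otherwise baseline).  For each pair of nodes X, Y
three structures are compared — X causes Y, Y causes X, no relationship —
by their Bayesian Dirichlet equivalent (BDe) marginal likelihoods under a
uniform structure prior.  The kinase-dead mutations are interventions: a
node set exogenously in a condition contributes no local-likelihood term
of its own in that case ("only the passively observed cases are
counted"), but still serves as an observed parent value.  This asymmetry
is what lets interventional data break the score equivalence of the two
directed structures, which purely observational data cannot.

Missing values are handled by available-case analysis per family term: a
case contributes to a family's counts iff the child and all parents are
observed in that case.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core_model import KINASES, RatioMatrix
from .errors import ValidationError

#: Discrete phosphorylation states.
UNDER, BASELINE, OVER = 0, 1, 2
MISSING = -1
N_STATES = 3
STATE_NAMES = {UNDER: "under", BASELINE: "baseline", OVER: "over", MISSING: "missing"}

#: Minimum |Pearson r| of the co-change pattern before a sign is assigned.
SIGN_R_THRESHOLD = 0.3


def discretize_ratio(ratio: float) -> int:
    """Three-state discretization on the strict 2-fold criterion."""
    if not np.isfinite(ratio):
        return MISSING
    if ratio < 0.5:
        return UNDER
    if ratio > 2.0:
        return OVER
    return BASELINE


def discretize(matrix: RatioMatrix) -> pd.DataFrame:
    """Discretize a replicate-collapsed ratio matrix (missing iff source missing)."""
    r = matrix.ratio.to_numpy(dtype=float)
    states = np.full(r.shape, BASELINE, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        states[r < 0.5] = UNDER
        states[r > 2.0] = OVER
    states[~np.isfinite(r)] = MISSING
    return pd.DataFrame(
        states, index=matrix.ratio.index, columns=matrix.ratio.columns
    )


def bde_family_score(
    child_states: np.ndarray,
    parent_states: np.ndarray | None = None,
    usable_mask: np.ndarray | None = None,
    prior_ess: float = 1.0,
) -> float:
    """Log marginal likelihood of one node's family under a BDeu prior.

    The Dirichlet hyperparameters split the equivalent sample size evenly:
    alpha_jk = prior_ess / (q * 3) for q parent configurations and three
    child states.  Counts come from usable cases only (caller excludes
    cases where the child is intervened or any family variable missing;
    by default cases with any MISSING state are dropped).  Zero usable
    cases give log-likelihood 0 (likelihood 1).
    """
    if prior_ess <= 0:
        raise ValidationError("prior_ess must be positive")
    child = np.asarray(child_states, dtype=int)
    if parent_states is not None:
        parent = np.asarray(parent_states, dtype=int)
        if parent.shape != child.shape:
            raise ValidationError("child and parent state vectors differ in length")
    else:
        parent = np.zeros_like(child)

    usable = (
        np.asarray(usable_mask, dtype=bool)
        if usable_mask is not None
        else np.ones_like(child, dtype=bool)
    )
    usable = usable & (child >= 0) & (parent >= 0)
    child, parent = child[usable], parent[usable]
    if child.size == 0:
        return 0.0

    q = N_STATES if parent_states is not None else 1
    counts = np.zeros((q, N_STATES))
    np.add.at(counts, (parent, child), 1.0)
    alpha_jk = prior_ess / (q * N_STATES)
    alpha_j = prior_ess / q
    n_j = counts.sum(axis=1)
    score = np.sum(gammaln(alpha_j) - gammaln(alpha_j + n_j))
    score += np.sum(gammaln(alpha_jk + counts) - gammaln(alpha_jk))
    return float(score)


STRUCTURES = ("x->y", "y->x", "independent")


@dataclass
class CausalPairResult:
    node_x: str
    node_y: str
    log_marginal: dict[str, float]
    posterior: dict[str, float]
    best_structure: str
    best_posterior: float
    n_usable_cases: dict[str, int]
    sign_annotation: str             # activating / inhibitory / undetermined
    proteins_x: tuple[str, ...] = ()
    proteins_y: tuple[str, ...] = ()


def _posteriors(log_marginal: Mapping[str, float]) -> dict[str, float]:
    keys = list(log_marginal)
    lm = np.array([log_marginal[k] for k in keys])
    w = np.exp(lm - lm.max())      # uniform structure prior cancels
    w /= w.sum()
    return dict(zip(keys, (float(v) for v in w)))


def _sign_annotation(x: np.ndarray, y: np.ndarray, joint: np.ndarray) -> str:
    if joint.sum() < 2:
        return "undetermined"
    xs, ys = x[joint].astype(float), y[joint].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return "undetermined"
    r = float(np.corrcoef(xs, ys)[0, 1])
    if r >= SIGN_R_THRESHOLD:
        return "activating"
    if r <= -SIGN_R_THRESHOLD:
        return "inhibitory"
    return "undetermined"


def score_pair(
    x_states: np.ndarray,
    y_states: np.ndarray,
    x_intervened: np.ndarray | None = None,
    y_intervened: np.ndarray | None = None,
    prior_ess: float = 1.0,
    node_x: str = "X",
    node_y: str = "Y",
) -> CausalPairResult | None:
    """Score the three structures between two nodes over the 8 cases.

    A case where a node is intervened drops that node's own family term
    but keeps the node as an observed parent value in the other node's
    term.  Returns None (undefined-result sentinel) when no case observes
    both nodes.
    """
    x = np.asarray(x_states, dtype=int)
    y = np.asarray(y_states, dtype=int)
    if x.shape != y.shape:
        raise ValidationError("state vectors differ in length")
    n = x.size
    x_int = np.zeros(n, bool) if x_intervened is None else np.asarray(x_intervened, bool)
    y_int = np.zeros(n, bool) if y_intervened is None else np.asarray(y_intervened, bool)

    obs_x, obs_y = x >= 0, y >= 0
    if not np.any(obs_x & obs_y):
        return None

    s_x = bde_family_score(x, None, ~x_int, prior_ess)
    s_y = bde_family_score(y, None, ~y_int, prior_ess)
    s_y_given_x = bde_family_score(y, x, ~y_int, prior_ess)
    s_x_given_y = bde_family_score(x, y, ~x_int, prior_ess)

    log_marginal = {
        "x->y": s_x + s_y_given_x,
        "y->x": s_y + s_x_given_y,
        "independent": s_x + s_y,
    }
    posterior = _posteriors(log_marginal)
    best = max(STRUCTURES, key=lambda k: posterior[k])
    n_usable = {
        "x->y": int((obs_x & ~x_int).sum() + (obs_x & obs_y & ~y_int).sum()),
        "y->x": int((obs_y & ~y_int).sum() + (obs_x & obs_y & ~x_int).sum()),
        "independent": int((obs_x & ~x_int).sum() + (obs_y & ~y_int).sum()),
    }
    return CausalPairResult(
        node_x=node_x,
        node_y=node_y,
        log_marginal=log_marginal,
        posterior=posterior,
        best_structure=best,
        best_posterior=posterior[best],
        n_usable_cases=n_usable,
        sign_annotation=_sign_annotation(x, y, obs_x & obs_y),
    )


def intervention_masks(
    states: pd.DataFrame,
    mapping: dict[str, frozenset[str]],
    intervention_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per (peptide, condition) flag: is this node set exogenously here?

    A kinase's own peptides are intervened exactly in that kinase's
    kinase-dead condition; peptides of non-kinase proteins are never
    intervened.
    """
    imap = dict(intervention_map or {k: k for k in KINASES})
    mask = pd.DataFrame(False, index=states.index, columns=states.columns)
    for condition in states.columns:
        kinase_protein = imap.get(condition)
        if kinase_protein is None:
            continue
        for key in states.index:
            if kinase_protein in mapping.get(key, frozenset()):
                mask.at[key, condition] = True
    return mask


def causal_screen(
    states: pd.DataFrame,
    mapping: dict[str, frozenset[str]],
    intervention_map: Mapping[str, str] | None = None,
    prior_ess: float = 1.0,
    report_threshold: float = 0.5,
) -> tuple[list[CausalPairResult], list[CausalPairResult]]:
    """Score all unordered peptide pairs among the focus set.

    Returns (all scored pairs, reported pairs).  A pair is reported when
    its best structure is directed with posterior strictly above
    ``report_threshold`` (ties at the threshold are not reported; two
    never-intervened nodes can never clear 0.5 by score equivalence).
    """
    if len(states) < 2:
        raise ValidationError("causal screen needs at least two focus peptides")
    masks = intervention_masks(states, mapping, intervention_map)
    results: list[CausalPairResult] = []
    reported: list[CausalPairResult] = []
    for key_a, key_b in combinations(states.index, 2):
        res = score_pair(
            states.loc[key_a].to_numpy(),
            states.loc[key_b].to_numpy(),
            masks.loc[key_a].to_numpy(),
            masks.loc[key_b].to_numpy(),
            prior_ess=prior_ess,
            node_x=key_a,
            node_y=key_b,
        )
        if res is None:
            continue
        res.proteins_x = tuple(sorted(mapping.get(key_a, frozenset())))
        res.proteins_y = tuple(sorted(mapping.get(key_b, frozenset())))
        results.append(res)
        if res.best_structure != "independent" and res.best_posterior > report_threshold:
            reported.append(res)
    return results, reported


def screen_to_frame(results: list[CausalPairResult]) -> pd.DataFrame:
    rows = [
        {
            "node_x": r.node_x,
            "node_y": r.node_y,
            "proteins_x": ";".join(r.proteins_x),
            "proteins_y": ";".join(r.proteins_y),
            "best_structure": r.best_structure,
            "best_posterior": r.best_posterior,
            "posterior_x_to_y": r.posterior["x->y"],
            "posterior_y_to_x": r.posterior["y->x"],
            "posterior_independent": r.posterior["independent"],
            "sign": r.sign_annotation,
            "n_usable_best": r.n_usable_cases[r.best_structure],
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "node_x", "node_y", "proteins_x", "proteins_y", "best_structure",
            "best_posterior", "posterior_x_to_y", "posterior_y_to_x",
            "posterior_independent", "sign", "n_usable_best",
        ],
    )


def write_causal_sif(reported: list[CausalPairResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reported:
            if r.best_structure == "x->y":
                fh.write(f"{r.node_x}\tcauses\t{r.node_y}\n")
            elif r.best_structure == "y->x":
                fh.write(f"{r.node_y}\tcauses\t{r.node_x}\n")


def write_causal_graphml(reported: list[CausalPairResult], path: str | Path) -> None:
    g = nx.DiGraph()
    for r in reported:
        if r.best_structure == "x->y":
            a, b = r.node_x, r.node_y
        elif r.best_structure == "y->x":
            a, b = r.node_y, r.node_x
        else:
            continue
        # edge width proportional to the posterior, per the usual drawing
        g.add_edge(a, b, posterior=r.best_posterior, sign=r.sign_annotation,
                   width=r.best_posterior)
    nx.write_graphml(g, path)
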