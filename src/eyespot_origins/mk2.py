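"""Asymmetric two-state continuous-time Markov model of a binary trait.

The model (often written Mk2 with unequal rates) has a gain rate
``q01`` (0 -> 1, per MY) and a loss rate ``q10`` (1 -> 0, per MY).  With
``s = q01 + q10`` and stationary frequency of state 1 ``pi1 = q01 / s``,
the transition probabilities over a branch of length ``t`` are in closed
form::

    P01(t) = pi1 * (1 - exp(-s t))       P00(t) = 1 - P01(t)
    P10(t) = (1 - pi1) * (1 - exp(-s t)) P11(t) = 1 - P10(t)

Likelihoods are computed by Felsenstein's pruning algorithm with per-node
rescaling.  Internal nodes may be *constrained* to a fixed state — the
partial likelihood of the disallowed state is zeroed before continuing
toward the root — which is how competing origin-number hypotheses are
scored.  Marginal ancestral states come from the standard up–down
(inside–outside) pass and equal the ratio of node-fixed likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log

import numpy as np
from scipy.optimize import minimize

from .trees import Chronogram

__all__ = [
    "Mk2Rates",
    "FitResult",
    "transition_matrix",
    "log_likelihood",
    "fit_rates",
    "marginal_ancestral_states",
]

RATE_LO = 1e-8
RATE_HI = 1e3

MISSING = -1  #: sentinel tip state for unavailable data


@dataclass(frozen=True)
class Mk2Rates:
    """Gain (0->1) and loss (1->0) rates, events per MY."""

    gain: float
    loss: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gain) and np.isfinite(self.loss)):
            raise ValueError("rates must be finite")
        if self.gain <= 0 or self.loss <= 0:
            raise ValueError("rates must be strictly positive")

    @property
    def stationary(self) -> tuple[float, float]:
        s = self.gain + self.loss
        return (self.loss / s, self.gain / s)


@dataclass
class FitResult:
    rates: Mk2Rates
    lnL: float
    converged: bool
    n_restarts_used: int


def transition_matrix(rates: Mk2Rates, t: float) -> np.ndarray:
    """2x2 transition probability matrix ``P[i, j] = P(j at time t | i at 0)``."""
    if t < 0:
        raise ValueError("elapsed time must be non-negative")
    s = rates.gain + rates.loss
    pi1 = rates.gain / s
    decay = 1.0 - exp(-s * t)
    p01 = pi1 * decay
    p10 = (1.0 - pi1) * decay
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def _resolve_root_prior(root_prior, rates: Mk2Rates) -> tuple[float, float]:
    if root_prior == "stationary" or root_prior is None:
        return rates.stationary
    if root_prior == "equal":
        return (0.5, 0.5)
    if root_prior in (0, 1, "0", "1"):
        st = int(root_prior)
        return (1.0, 0.0) if st == 0 else (0.0, 1.0)
    if isinstance(root_prior, (tuple, list)) and len(root_prior) == 2:
        p0, p1 = float(root_prior[0]), float(root_prior[1])
        if p0 < 0 or p1 < 0 or abs(p0 + p1 - 1.0) > 1e-9:
            raise ValueError("root prior must be a probability vector")
        return (p0, p1)
    raise ValueError(f"unrecognized root prior: {root_prior!r}")


def _tip_states(tree: Chronogram, char: dict[str, int]) -> list[int]:
    """Per-node tip state vector; MISSING for internal nodes and absent taxa."""
    states = [MISSING] * tree.n_nodes
    n_observed = 0
    for tip in tree.tip_ids:
        label = tree.labels[tip]
        st = char.get(label, None)
        if st is None or (isinstance(st, float) and np.isnan(st)):
            continue
        st = int(st)
        if st not in (0, 1):
            raise ValueError(f"tip {label!r} has non-binary state {st!r}")
        states[tip] = st
        n_observed += 1
    if n_observed == 0:
        raise ValueError("all tip states are missing; likelihood is undefined")
    return states


def _check_constraints(
    tree: Chronogram, constraints: dict[int, int] | None, tip_states: list[int]
) -> dict[int, int]:
    if not constraints:
        return {}
    out: dict[int, int] = {}
    for node, st in constraints.items():
        node = int(node)
        if node < 0 or node >= tree.n_nodes:
            raise ValueError(f"constraint on nonexistent node {node}")
        if st not in (0, 1):
            raise ValueError(f"constraint state must be 0 or 1, got {st!r}")
        if node in out:
            raise ValueError(f"node {node} constrained twice")
        if tree.is_tip(node) and tip_states[node] != MISSING and tip_states[node] != st:
            raise ValueError(
                f"constraint on tip {tree.labels[node]!r} contradicts its observed state"
            )
        out[node] = int(st)
    return out


def _edge_probs(rates: Mk2Rates, lengths: np.ndarray) -> list[tuple[float, float, float, float]]:
    s = rates.gain + rates.loss
    pi1 = rates.gain / s
    decay = 1.0 - np.exp(-s * np.asarray(lengths, dtype=float))
    p01 = pi1 * decay
    p10 = (1.0 - pi1) * decay
    return list(zip(1.0 - p01, p01, p10, 1.0 - p10))


def _down_pass(tree, tip_states, constraints, rates):
    """Normalized downward partials and the accumulated log scale.

    Returns ``(partials, log_scale, edge_p)`` where ``partials[v]`` is the
    rescaled ``(L0, L1)`` conditional on the subtree below ``v`` and
    ``log_scale`` restores the true log-likelihood magnitude at the root.
    """
    edge_p = _edge_probs(rates, np.nan_to_num(tree.branch_length, nan=0.0))
    children = tree.children
    partials: list[tuple[float, float]] = [None] * tree.n_nodes  # type: ignore
    log_scale = 0.0
    for v in tree.postorder():
        kids = children[v]
        if not kids:
            st = tip_states[v]
            if st == MISSING:
                l0, l1 = 1.0, 1.0
            elif st == 0:
                l0, l1 = 1.0, 0.0
            else:
                l0, l1 = 0.0, 1.0
        else:
            l0, l1 = 1.0, 1.0
            for c in kids:
                p00, p01, p10, p11 = edge_p[c]
                c0, c1 = partials[c]
                l0 *= p00 * c0 + p01 * c1
                l1 *= p10 * c0 + p11 * c1
        st = constraints.get(v)
        if st == 0:
            l1 = 0.0
        elif st == 1:
            l0 = 0.0
        m = l0 if l0 > l1 else l1
        if m <= 0.0:
            return None, -np.inf, edge_p  # contradictory constraints
        partials[v] = (l0 / m, l1 / m)
        log_scale += log(m)
    return partials, log_scale, edge_p


def log_likelihood(
    tree: Chronogram,
    char: dict[str, int],
    rates: Mk2Rates,
    constraints: dict[int, int] | None = None,
    root_prior="stationary",
) -> float:
    """Log-likelihood of tip states under the asymmetric two-rate model.

    Missing tips contribute partials ``(1, 1)``; constrained internal nodes
    are conditioned on their fixed state (the other state's partial is
    zeroed).  The root partials are dotted with ``root_prior`` (default:
    stationary distribution of the rate matrix).
    """
    tip_states = _tip_states(tree, char)
    cons = _check_constraints(tree, constraints, tip_states)
    prior = _resolve_root_prior(root_prior, rates)
    partials, log_scale, _ = _down_pass(tree, tip_states, cons, rates)
    if partials is None:
        return -np.inf
    r0, r1 = partials[tree.root]
    lik = prior[0] * r0 + prior[1] * r1
    if lik <= 0.0:
        return -np.inf
    return log(lik) + log_scale


def fit_rates(
    tree: Chronogram,
    char: dict[str, int],
    constraints: dict[int, int] | None = None,
    root_prior="stationary",
    n_restarts: int = 5,
    seed: int | None = 0,
) -> FitResult:
    """Maximum-likelihood gain/loss rates by bounded quasi-Newton search.

    Optimization runs in log-rate space (the surface for rare events is
    flat and can be multimodal) from ``n_restarts`` starting points: one
    heuristic start at one event per tree height, the rest drawn log-
    uniformly from the bounded box, deterministically from ``seed``.
    """
    tip_states = _tip_states(tree, char)
    cons = _check_constraints(tree, constraints, tip_states)
    height = float(np.nanmax(tree.depths()[tree.tip_ids])) or 1.0

    def neg_lnL(logq: np.ndarray) -> float:
        rates = Mk2Rates(float(np.exp(logq[0])), float(np.exp(logq[1])))
        prior = _resolve_root_prior(root_prior, rates)
        partials, log_scale, _ = _down_pass(tree, tip_states, cons, rates)
        if partials is None:
            return 1e12
        r0, r1 = partials[tree.root]
        lik = prior[0] * r0 + prior[1] * r1
        if lik <= 0.0:
            return 1e12
        return -(log(lik) + log_scale)

    rng = np.random.default_rng(seed)
    lo, hi = log(RATE_LO), log(RATE_HI)
    starts = [np.log([1.0 / height, 1.0 / height])]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.uniform(log(1e-4), log(10.0), size=2))
    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            neg_lnL, np.clip(x0, lo, hi), method="L-BFGS-B",
            bounds=[(lo, hi), (lo, hi)],
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    rates = Mk2Rates(float(np.exp(best.x[0])), float(np.exp(best.x[1])))
    return FitResult(
        rates=rates, lnL=-float(best.fun),
        converged=any_converged, n_restarts_used=len(starts),
    )


def marginal_ancestral_states(
    tree: Chronogram,
    char: dict[str, int],
    rates: Mk2Rates,
    root_prior="stationary",
    constraints: dict[int, int] | None = None,
) -> dict[int, tuple[float, float]]:
    """Marginal posterior ``(p0, p1)`` for every internal node.

    Combines the downward (pruning) partials with upward partials covering
    the data outside each node's subtree; at every node the result equals
    the normalized pair of likelihoods with that node fixed to each state.
    """
    tip_states = _tip_states(tree, char)
    cons = _check_constraints(tree, constraints, tip_states)
    prior = _resolve_root_prior(root_prior, rates)
    down, _, edge_p = _down_pass(tree, tip_states, cons, rates)
    if down is None:
        raise ValueError("constraints have zero likelihood; no posterior exists")

    # msg[c][i]: P(data below c | parent of c in state i), unnormalized.
    msg: list[tuple[float, float]] = [None] * tree.n_nodes  # type: ignore
    for v in range(tree.n_nodes - 1):
        p00, p01, p10, p11 = edge_p[v]
        d0, d1 = down[v]
        msg[v] = (p00 * d0 + p01 * d1, p10 * d0 + p11 * d1)

    # Constraint masks applied at the node itself, for the upward pass.
    def mask(v: int) -> tuple[float, float]:
        st = cons.get(v)
        if st == 0:
            return (1.0, 0.0)
        if st == 1:
            return (0.0, 1.0)
        return (1.0, 1.0)

    up: list[tuple[float, float]] = [None] * tree.n_nodes  # type: ignore
    up[tree.root] = prior
    for v in range(tree.n_nodes - 1, -1, -1):  # preorder
        if tree.is_tip(v):
            continue
        u0, u1 = up[v]
        m0, m1 = mask(v)
        u0 *= m0
        u1 *= m1
        kids = tree.children[v]
        for c in kids:
            s0, s1 = u0, u1
            for sib in kids:
                if sib is not c:
                    t0, t1 = msg[sib]
                    s0 *= t0
                    s1 *= t1
            p00, p01, p10, p11 = edge_p[c]
            uc0 = p00 * s0 + p10 * s1
            uc1 = p01 * s0 + p11 * s1
            z = max(uc0, uc1)
            up[c] = (uc0 / z, uc1 / z) if z > 0 else (0.0, 0.0)

    out: dict[int, tuple[float, float]] = {}
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            continue
        g0 = up[v][0] * down[v][0]
        g1 = up[v][1] * down[v][1]
        z = g0 + g1
        if z <= 0:
            raise ValueError(f"zero posterior mass at node {v}")
        out[v] = (g0 / z, g1 / z)
    return out
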