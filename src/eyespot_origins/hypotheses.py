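"""Origin-number hypotheses as node-constraint sets, and their comparison.

A hypothesis about how many times a binary trait arose is encoded by fixing
ancestral states at named internal nodes (e.g. a single-origin model fixes
the focal clade's ancestor to 1 and deeper nodes to 0).  Each model is
scored by maximum likelihood under the asymmetric two-rate model, and models
are compared on raw log-likelihood differences: a model whose lnL falls two
or more log-units below the best fit is rejected.  The two-unit rule is
used verbatim rather than a chi-square LRT because competing models differ
in node constraints, not in parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import mk2
from .trees import Chronogram, parse_node_spec

__all__ = [
    "OriginModel",
    "evaluate_models",
    "count_origins",
    "read_model_file",
    "OriginCount",
]

#: Log-likelihood difference at or above which a model is rejected.
DECISION_DELTA = 2.0


@dataclass
class OriginModel:
    """A named hypothesis: internal nodes fixed to ancestral states."""

    name: str
    constraints: dict[int, int]
    fit: mk2.FitResult | None = None


def read_model_file(tree: Chronogram, path) -> list[OriginModel]:
    """Read models from delimited text: ``model_name, node_spec, state``.

    ``node_spec`` addresses an internal node as the mrca of two tips,
    written ``"A|B"`` (a single label addresses that tip).
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#",
                     names=["model", "node", "state"], header=None, skipinitialspace=True)
    models: dict[str, OriginModel] = {}
    for _, row in df.iterrows():
        name = str(row["model"])
        node = parse_node_spec(tree, str(row["node"]))
        model = models.setdefault(name, OriginModel(name=name, constraints={}))
        if node in model.constraints:
            raise ValueError(f"model {name!r} constrains node {row['node']!r} twice")
        model.constraints[node] = int(row["state"])
    return list(models.values())


def evaluate_models(
    tree: Chronogram,
    char: dict[str, int],
    models: list[OriginModel],
    shared_rates: bool = False,
    root_prior="stationary",
    n_restarts: int = 5,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Fit each constrained model and build the comparison table.

    By default rates are re-optimized under every model's constraints (the
    conservative choice); with ``shared_rates=True`` the unconstrained MLE
    rates are estimated once and every model is scored at those rates.

    Returns a DataFrame with columns ``model, constraints, lnL, delta_lnL,
    rejected``; the best model has ``delta_lnL == 0`` and is never rejected.
    """
    if not models:
        raise ValueError("at least one model is required")
    shared = None
    if shared_rates:
        shared = mk2.fit_rates(tree, char, None, root_prior, n_restarts, seed)
    for model in models:
        if shared is not None:
            lnL = mk2.log_likelihood(tree, char, shared.rates, model.constraints, root_prior)
            model.fit = mk2.FitResult(shared.rates, lnL, shared.converged, 0)
        else:
            model.fit = mk2.fit_rates(
                tree, char, model.constraints, root_prior, n_restarts, seed
            )
    return comparison_table(models)


def comparison_table(models: list[OriginModel]) -> pd.DataFrame:
    """Tabulate fitted models against the best by the two-log-unit rule."""
    if not models:
        raise ValueError("empty model list")
    best = max(m.fit.lnL for m in models)
    rows = []
    for m in models:
        delta = best - m.fit.lnL
        rows.append({
            "model": m.name,
            "constraints": ";".join(
                f"{node}={st}" for node, st in sorted(m.constraints.items())
            ),
            "gain": m.fit.rates.gain,
            "loss": m.fit.rates.loss,
            "lnL": m.fit.lnL,
            "delta_lnL": delta,
            "rejected": delta >= DECISION_DELTA,
        })
    return pd.DataFrame(rows)


@dataclass
class OriginCount:
    """Number of 0 -> 1 transitions implied by an ancestral reconstruction.

    ``min_count``/``max_count`` bracket the count when some nodes are
    ambiguous (marginal posterior exactly 1/2); they coincide otherwise.
    ``root_stem_origin`` flags a root reconstructed in state 1, i.e. an
    origin that predates the root and cannot be placed on any edge.
    """

    min_count: int
    max_count: int
    root_stem_origin: bool
    ambiguous_nodes: list[int] = field(default_factory=list)

    @property
    def count(self) -> int:
        if self.min_count != self.max_count:
            raise ValueError("origin count is ambiguous; inspect min/max")
        return self.min_count


_TIE_EPS = 1e-9


def count_origins(
    tree: Chronogram,
    reconstruction: dict[int, tuple[float, float]],
    char: dict[str, int],
) -> OriginCount:
    """Count parent(0) -> child(1) edges under maximum-posterior states.

    Internal nodes take state 1 when their marginal p1 >= 0.5 (ties, within
    1e-9 of exactly 0.5, are treated as ambiguous, never broken silently);
    tips take their observed state and missing tips are excluded.  With
    ambiguous nodes the count is reported as an interval over all their
    resolutions.
    """
    states: dict[int, int | None] = {}
    ambiguous: list[int] = []
    for tip in tree.tip_ids:
        st = char.get(tree.labels[tip], None)
        if st is None or (isinstance(st, float) and pd.isna(st)):
            continue
        states[tip] = int(st)
    for node, (p0, p1) in reconstruction.items():
        if abs(p1 - 0.5) <= _TIE_EPS:
            states[node] = None
            ambiguous.append(node)
        else:
            states[node] = 1 if p1 > 0.5 else 0

    edges = [
        (int(tree.parent[v]), v)
        for v in range(tree.n_nodes - 1)
        if v in states and int(tree.parent[v]) in states
    ]

    def count_for(assign: dict[int, int]) -> int:
        return sum(1 for p, c in edges if assign[p] == 0 and assign[c] == 1)

    if not ambiguous:
        resolved = {v: s for v, s in states.items() if s is not None}
        n = count_for(resolved)
        root_state = states.get(tree.root)
        return OriginCount(n, n, root_stem_origin=(root_state == 1))

    if len(ambiguous) <= 12:
        lo, hi = None, None
        for bits in range(2 ** len(ambiguous)):
            assign = dict(states)
            for k, node in enumerate(ambiguous):
                assign[node] = (bits >> k) & 1
            n = count_for(assign)  # type: ignore[arg-type]
            lo = n if lo is None else min(lo, n)
            hi = n if hi is None else max(hi, n)
    else:
        # Too many ties to enumerate: bound by definite vs. possible origins.
        lo = sum(1 for p, c in edges if states[p] == 0 and states[c] == 1)
        hi = sum(
            1 for p, c in edges
            if states[p] in (0, None) and states[c] in (1, None)
        )
    root_state = states.get(tree.root)
    return OriginCount(
        int(lo), int(hi),
        root_stem_origin=(root_state == 1),
        ambiguous_nodes=ambiguous,
    )
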