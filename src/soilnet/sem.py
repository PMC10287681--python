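"""Piecewise path models and the relative-contribution ledger.

A path model here is a DAG over observed variables, fit equation by
equation: every endogenous variable is regressed on its parents with a
random intercept on the experimental grouping (sowing density), all
variables standardized so coefficients are betas.  Overall fit uses
Shipley's d-separation test: the basis set of independence claims implied
by the missing edges, each tested by regression, combined as Fisher's
C = -2 sum ln p ~ chi-square(2k).  Model selection is backward stepwise
elimination of the weakest edge with the small-sample AIC (AICc) summed
over component equations; the AICc-minimal model along the path wins.

The contribution ledger aggregates, over a collection of fitted models (one
per microbial response), the absolute standardized effect of every retained
significant pathway weighted by the relative size of the microbial variable
it reaches — direct plant->microbe paths as |beta| * size, indirect
plant->chemistry->microbe paths as |beta_pc * beta_cm| * size — grouped by
(year/past) x (overall/compositional) x (direct/indirect) and scaled by the
number of candidate pathways per group.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coupling import apply_transform, choose_transform
from .errors import DataError, SpecificationError
from .lmm import fit_random_intercept

logger = logging.getLogger(__name__)

__all__ = [
    "PathSpec",
    "EquationFit",
    "FittedPathModel",
    "ContributionLedger",
    "CHEM_MEDIATORS",
    "fit_equation",
    "dsep_basis_set",
    "evaluate_claims",
    "fishers_c",
    "aicc",
    "backward_eliminate",
    "build_and_run_sems",
    "relative_contributions",
]

#: Soil chemical mediators every base model includes.
CHEM_MEDIATORS = [
    "total_n",
    "organic_c",
    "ph",
    "avail_p",
    "no3",
    "nh4",
    "no2",
    "belowground_productivity",
]

#: Plant parameters by (time, component) role.
PLANT_ROLES = {
    "productivity": ("year", "overall"),
    "diversity": ("year", "overall"),
    "axis1": ("year", "compositional"),
    "axis2": ("year", "compositional"),
    "axis3": ("year", "compositional"),
    "impact_productivity": ("past", "overall"),
    "impact_diversity": ("past", "overall"),
    "trajectory_productivity": ("past", "overall"),
    "trajectory_diversity": ("past", "overall"),
    "impact_axis1": ("past", "compositional"),
    "impact_axis2": ("past", "compositional"),
    "impact_axis3": ("past", "compositional"),
    "trajectory_axis1": ("past", "compositional"),
    "trajectory_axis2": ("past", "compositional"),
    "trajectory_axis3": ("past", "compositional"),
}


@dataclass
class PathSpec:
    """Candidate DAG: exogenous plant variables, chemical mediators, one
    microbial response, and the candidate directed edges."""

    plant_vars: list
    mediators: list
    response: str | None
    edges: list  # (src, dst) tuples
    grouping: str = "sowing_density"
    roles: dict = field(default_factory=lambda: dict(PLANT_ROLES))

    def __post_init__(self) -> None:
        nodes = set(self.plant_vars) | set(self.mediators)
        if self.response is not None:
            nodes.add(self.response)
        for s, d in self.edges:
            if s not in nodes or d not in nodes:
                raise SpecificationError(f"edge ({s}, {d}) references unknown node")
        if not _is_acyclic(nodes, self.edges):
            raise SpecificationError("path specification is cyclic")

    @property
    def nodes(self) -> list:
        out = list(self.plant_vars) + list(self.mediators)
        if self.response is not None:
            out.append(self.response)
        return out

    def edge_group(self, edge) -> tuple | None:
        """Ledger group of a candidate edge: plant->response is direct,
        plant->mediator seeds indirect pathways; mediator->response is the
        second leg of indirect pathways (no group of its own)."""
        s, d = edge
        if s in self.roles and d == self.response:
            return (*self.roles[s], "direct")
        return None


@dataclass
class EquationFit:
    response: str
    predictors: list
    beta: pd.Series
    se: pd.Series
    p: pd.Series
    n: int
    loglik: float
    k_params: int
    aicc: float
    transform: str
    mixed: bool


@dataclass
class FittedPathModel:
    spec: PathSpec
    edges: list  # retained (src, dst)
    equations: dict  # response -> EquationFit
    claims: list  # (x, y, cond, p)
    fisher_c: float
    df: int
    model_p: float
    aicc: float
    n: int
    history: list  # (step, removed_edge | None, aicc)

    def edge_beta(self, edge) -> float:
        s, d = edge
        return float(self.equations[d].beta[s])

    def edge_p(self, edge) -> float:
        s, d = edge
        return float(self.equations[d].p[s])


@dataclass
class ContributionLedger:
    raw: dict  # group tuple -> summed weighted contribution
    scaled: dict  # raw / potential pathway count
    potential: dict  # group tuple -> candidate pathway count
    alpha: float

    GROUPS = [
        (t, c, d)
        for t in ("year", "past")
        for c in ("overall", "compositional")
        for d in ("direct", "indirect")
    ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"time": t, "component": c, "kind": d,
             "raw": self.raw[(t, c, d)], "potential": self.potential[(t, c, d)],
             "scaled": self.scaled[(t, c, d)]}
            for (t, c, d) in self.GROUPS
        ]
        return pd.DataFrame(rows)


def _is_acyclic(nodes, edges) -> bool:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return nx.is_directed_acyclic_graph(g)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise DataError("constant variable cannot be standardized")
    return (v - v.mean()) / sd


def fit_equation(
    data: pd.DataFrame,
    response: str,
    predictors: list,
    grouping: str | None = None,
    transform: str = "auto",
) -> EquationFit:
    """One component regression: standardized response on standardized
    predictors, random intercept on ``grouping`` when it has >= 2 levels and
    >= 3 observations per level (plain least squares otherwise).  Fit by ML
    so AICc values are comparable across elimination steps.
    """
    import statsmodels.api as sm

    n = len(data)
    if n <= len(predictors) + 2:
        raise DataError(
            f"n = {n} too small for {len(predictors)} predictors"
        )
    y_raw = data[response].to_numpy(dtype=float)
    if transform == "auto" and predictors:
        x0 = data[predictors[0]].to_numpy(dtype=float)
        t = choose_transform(y_raw, x0)
    elif transform == "auto":
        t = "none"
    else:
        t = transform
    y = _zscore(apply_transform(y_raw, t))
    X = np.column_stack(
        [_zscore(data[p].to_numpy(dtype=float)) for p in predictors]
    ) if predictors else np.empty((n, 0))
    if predictors:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise DataError(f"collinear predictors among {predictors}")
    exog = sm.add_constant(X, has_constant="add")

    use_mixed = False
    groups = None
    if grouping is not None and grouping in data:
        groups = data[grouping]
        counts = groups.value_counts()
        use_mixed = len(counts) >= 2 and counts.min() >= 3

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if use_mixed:
            try:
                fit = fit_random_intercept(y, exog, groups.to_numpy())
                loglik = float(fit.llf)
                k = exog.shape[1] + 2  # fixed effects + resid var + RE var
                beta = pd.Series(fit.params[1 : 1 + len(predictors)], index=predictors)
                se = pd.Series(fit.bse[1 : 1 + len(predictors)], index=predictors)
                pvals = pd.Series(
                    fit.pvalues[1 : 1 + len(predictors)], index=predictors
                )
                return EquationFit(response, list(predictors), beta, se, pvals,
                                   n, loglik, k, aicc(loglik, n, k), t, True)
            except Exception as exc:
                logger.debug("mixed fit failed for %s (%s); OLS fallback",
                             response, exc)
        fit = sm.OLS(y, exog).fit()
        loglik = float(fit.llf)
        k = exog.shape[1] + 1  # + residual variance
        beta = pd.Series(fit.params[1:], index=predictors)
        se = pd.Series(fit.bse[1:], index=predictors)
        pvals = pd.Series(fit.pvalues[1:], index=predictors)
        return EquationFit(response, list(predictors), beta, se, pvals,
                           n, loglik, k, aicc(loglik, n, k), t, False)


def aicc(loglik: float, n: int, k_params: int) -> float:
    """AIC + small-sample correction 2k(k+1)/(n-k-1)."""
    if n <= k_params + 1:
        raise DataError(f"AICc undefined for n = {n}, k = {k_params}")
    aic = -2.0 * loglik + 2.0 * k_params
    return aic + 2.0 * k_params * (k_params + 1) / (n - k_params - 1)


def dsep_basis_set(nodes: list, edges: list) -> list:
    """Shipley basis set of the DAG's missing edges.

    For every non-adjacent ordered pair (x before y topologically) the claim
    is x independent of y given parents(x) union parents(y).  Ordering is
    deterministic (topological position, then name).
    """
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise SpecificationError("graph is cyclic")
    topo = list(nx.lexicographical_topological_sort(g, key=str))
    pos = {n: i for i, n in enumerate(topo)}
    parents = {n: set(g.predecessors(n)) for n in g.nodes}
    adjacent = {frozenset((u, v)) for u, v in g.edges}
    claims = []
    for x, y in itertools.combinations(topo, 2):
        if frozenset((x, y)) in adjacent:
            continue
        cond = sorted((parents[x] | parents[y]) - {x, y}, key=str)
        claims.append((x, y, tuple(cond)))
    claims.sort(key=lambda c: (pos[c[0]], pos[c[1]]))
    return claims


def evaluate_claims(
    claims: list,
    data: pd.DataFrame,
    grouping: str | None = None,
    transform: str = "none",
) -> list:
    """Regression test of each claim: p-value of x in y ~ x + conditioning
    set.  Returns (x, y, cond, p) tuples."""
    out = []
    for x, y, cond in claims:
        fit = fit_equation(data, y, [x, *cond], grouping=grouping,
                          transform=transform)
        out.append((x, y, cond, float(fit.p[x])))
    return out


def fishers_c(p_values) -> tuple[float, int, float]:
    """C = -2 sum ln p, df = 2k, model p = chi-square upper tail."""
    ps = np.asarray(list(p_values), dtype=float)
    if len(ps) == 0:
        return 0.0, 0, 1.0
    if np.any(ps < 0) or np.any(ps > 1):
        raise DataError("claim p-values must lie in (0, 1]")
    if np.any(ps == 0):
        logger.warning("claim p-value of 0 clamped to machine minimum")
        ps = np.maximum(ps, np.finfo(float).tiny)
    c = float(-2.0 * np.log(ps).sum())
    df = 2 * len(ps)
    return c, df, float(stats.chi2.sf(c, df))


def _model_fit(
    spec: PathSpec, data: pd.DataFrame, edges: list, transform: str
) -> tuple[dict, float]:
    """Fit every endogenous equation given the retained edge set; returns
    equations and the summed AICc.  Endogenous variables without retained
    parents contribute intercept-only equations, keeping AICc sums
    comparable across steps."""
    endogenous = [v for v in spec.nodes if v not in spec.plant_vars]
    equations = {}
    total = 0.0
    for v in endogenous:
        parents = [s for s, d in edges if d == v]
        eq = fit_equation(data, v, parents, grouping=spec.grouping,
                          transform=transform)
        equations[v] = eq
        total += eq.aicc
    return equations, total


def backward_eliminate(
    spec: PathSpec,
    data: pd.DataFrame,
    transform: str = "auto",
    dsep_transform: str = "none",
    compute_dsep: bool = True,
) -> FittedPathModel:
    """Backward stepwise elimination to the AICc-minimal model.

    At each step the retained edge with the highest p-value is removed (ties
    broken by the smaller |beta|) and the model refit, until no edges
    remain; the step with the lowest summed AICc is returned, with the
    d-separation test evaluated on its DAG.
    """
    missing = [v for v in spec.nodes if v not in data.columns]
    if missing:
        raise DataError(f"data missing variables: {missing}")
    edges = list(spec.edges)
    history = []
    snapshots = []
    step = 0
    equations, total = _model_fit(spec, data, edges, transform)
    history.append((step, None, total))
    snapshots.append((list(edges), equations))
    while edges:
        worst = max(
            edges,
            key=lambda e: (equations[e[1]].p[e[0]], -abs(equations[e[1]].beta[e[0]])),
        )
        edges = [e for e in edges if e != worst]
        step += 1
        # only the equation that lost a parent changes
        resp = worst[1]
        parents = [s for s, d in edges if d == resp]
        equations = dict(equations)
        equations[resp] = fit_equation(data, resp, parents,
                                       grouping=spec.grouping,
                                       transform=transform)
        total = sum(eq.aicc for eq in equations.values())
        history.append((step, worst, total))
        snapshots.append((list(edges), equations))

    aiccs = [h[2] for h in history]
    best = int(np.argmin(aiccs))
    best_edges, best_eqs = snapshots[best]

    if compute_dsep:
        claims = dsep_basis_set(spec.nodes, best_edges)
        tested = evaluate_claims(claims, data, grouping=spec.grouping,
                             transform=dsep_transform)
        c, df, model_p = fishers_c([p for *_, p in tested])
    else:
        tested, (c, df, model_p) = [], (np.nan, 0, np.nan)
    return FittedPathModel(
        spec=spec,
        edges=best_edges,
        equations=best_eqs,
        claims=tested,
        fisher_c=c,
        df=df,
        model_p=model_p,
        aicc=aiccs[best],
        n=len(data),
        history=history,
    )


def _base_spec(plant_vars: list, grouping: str) -> PathSpec:
    edges = [(p, c) for p in plant_vars for c in CHEM_MEDIATORS]
    return PathSpec(plant_vars=plant_vars, mediators=list(CHEM_MEDIATORS),
                    response=None, edges=edges, grouping=grouping)


def microbial_spec(
    plant_vars: list,
    base_edges: list,
    response: str,
    grouping: str = "sowing_density",
) -> PathSpec:
    """Candidate model for one microbial response: the combined base's
    plant->chemistry edges plus every chemistry->microbe and direct
    plant->microbe edge."""
    edges = list(base_edges)
    edges += [(c, response) for c in CHEM_MEDIATORS]
    edges += [(p, response) for p in plant_vars]
    return PathSpec(plant_vars=list(plant_vars), mediators=list(CHEM_MEDIATORS),
                    response=response, edges=edges, grouping=grouping)


def build_and_run_sems(
    data: pd.DataFrame,
    microbial_vars: list,
    soil_col: str = "soil",
    grouping: str = "sowing_density",
    plant_roles: dict | None = None,
    transform: str = "auto",
    compute_dsep: bool = True,
) -> dict:
    """Per soil: three backward-eliminated base models (year, past-overall,
    past-compositional plant effects on chemistry), merged by the union of
    retained plant->chemistry edges, then one full model per microbial
    variable.  Returns {soil: {microbial_var: FittedPathModel}}."""
    roles = plant_roles or PLANT_ROLES
    year_vars = [v for v, r in roles.items() if r[0] == "year" and v in data]
    past_overall = [v for v, r in roles.items()
                    if r == ("past", "overall") and v in data]
    past_comp = [v for v, r in roles.items()
                 if r == ("past", "compositional") and v in data]
    missing = [v for v in microbial_vars if v not in data.columns]
    if missing:
        raise DataError(f"microbial variables missing: {missing}")

    results: dict = {}
    for soil, sub in data.groupby(soil_col, sort=True):
        sub = sub.reset_index(drop=True)
        base_edges: list = []
        for plant_vars in (year_vars, past_overall, past_comp):
            if not plant_vars:
                continue
            model = backward_eliminate(_base_spec(plant_vars, grouping), sub,
                                       transform=transform, compute_dsep=False)
            base_edges.extend(e for e in model.edges if e not in base_edges)
        plant_all = year_vars + past_overall + past_comp
        results[soil] = {}
        for mv in microbial_vars:
            spec = microbial_spec(plant_all, base_edges, mv, grouping=grouping)
            results[soil][mv] = backward_eliminate(
                spec, sub, transform=transform, compute_dsep=compute_dsep
            )
    return results


def relative_contributions(
    models: dict,
    sizes: dict,
    alpha: float = 0.05,
) -> ContributionLedger:
    """Aggregate the Fig-5b-style contribution ledger over fitted models.

    ``models``: {soil: {microbial_var: FittedPathModel}} (or a flat
    {microbial_var: model} mapping); ``sizes``: relative size in (0, 1] of
    each microbial variable, keyed like the models ((soil, var) or var).
    """
    flat: list[tuple[tuple, FittedPathModel]] = []
    for k, v in models.items():
        if isinstance(v, dict):
            for mv, m in v.items():
                flat.append(((k, mv), m))
        else:
            flat.append(((k,), m := v))

    def size_of(key):
        for probe in (key, key[-1]):
            if probe in sizes:
                s = float(sizes[probe])
                if not 0 < s <= 1:
                    raise DataError(f"size for {probe!r} must be in (0, 1]")
                return s
        raise DataError(f"no size weight for microbial variable {key!r}")

    raw = {g: 0.0 for g in ContributionLedger.GROUPS}
    potential = {g: 0 for g in ContributionLedger.GROUPS}
    for key, model in flat:
        size = size_of(key)
        spec = model.spec
        roles = spec.roles
        resp = spec.response
        # candidate pathway counts (pre-elimination)
        for s, d in spec.edges:
            if s in roles and d == resp:
                potential[(*roles[s], "direct")] += 1
        cand_pc = [(s, d) for s, d in spec.edges if s in roles and d in spec.mediators]
        cand_cm = {s for s, d in spec.edges if s in spec.mediators and d == resp}
        for s, d in cand_pc:
            if d in cand_cm:
                potential[(*roles[s], "indirect")] += 1
        # realized significant pathways
        retained = set(model.edges)
        for s, d in retained:
            if s in roles and d == resp and model.edge_p((s, d)) < alpha:
                raw[(*roles[s], "direct")] += abs(model.edge_beta((s, d))) * size
        for s, c in retained:
            if s in roles and c in spec.mediators and (c, resp) in retained:
                if model.edge_p((s, c)) < alpha and model.edge_p((c, resp)) < alpha:
                    b = model.edge_beta((s, c)) * model.edge_beta((c, resp))
                    raw[(*roles[s], "indirect")] += abs(b) * size

    scaled = {
        g: (raw[g] / potential[g] if potential[g] else 0.0)
        for g in ContributionLedger.GROUPS
    }
    return ContributionLedger(raw=raw, scaled=scaled, potential=potential,
                              alpha=alpha)


def count_sem_models(inventory: dict) -> int:
    """Number of unique path models: one per microbial variable per soil.

    ``inventory``: {soil: {kind: count}} e.g. biomass pools and per-domain
    cluster counts."""
    return sum(sum(kinds.values()) for kinds in inventory.values())
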