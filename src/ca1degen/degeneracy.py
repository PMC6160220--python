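"""Degeneracy analyses over ensembles of optimized individuals.

Given hall-of-fame individuals pooled across optimization runs, this module
quantifies how the same firing behaviour is realized by different channel
configurations: per-parameter stability (normalized sd < 0.2), pairwise
Spearman correlations between peak conductances (flagged at |rho| > 0.25 and
p < 0.05, mirroring the reduced correlation tables), per-channel proportions
of the total average peak conductance, nonparametric e-type comparisons
(Kruskal–Wallis + Dunn's pairwise test at p < 0.05 with direction), transfer
of a fixed conductance set across morphologies, input/output (f–I) curves
with Mann–Whitney comparisons, and classification of backpropagating-AP
attenuation profiles.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .morphology import Morphology, morphometrics
from .objectives import ObjectiveSet, ScoreReport

__all__ = [
    "ParameterMatrix",
    "DegeneracyReport",
    "analyze_individuals",
    "normalize_parameter_matrix",
    "stability_analysis",
    "spearman_with_p",
    "pairwise_spearman",
    "channel_proportions",
    "etype_comparison",
    "dunn_test",
    "morphology_transfer",
    "io_curves",
    "bap_attenuation_analysis",
]

RHO_THRESHOLD = 0.25
STABILITY_SD = 0.2
ALPHA = 0.05


@dataclass
class ParameterMatrix:
    """Individuals × parameters, raw and per-column normalized forms.

    Normalization divides each column by its maximum across all individuals
    of the e-type; all-zero columns stay zero and are flagged.
    """

    etype: str
    parameter_names: list[str]
    raw: np.ndarray  # (n_individuals, n_parameters)
    run_ids: list = field(default_factory=list)
    normalized: np.ndarray | None = None
    column_max: np.ndarray | None = None
    zero_columns: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.raw.shape[0]

    def column(self, name: str, normalized: bool = True) -> np.ndarray:
        j = self.parameter_names.index(name)
        return (self.normalized if normalized else self.raw)[:, j]

    def to_frame(self, normalized: bool = True) -> pd.DataFrame:
        return pd.DataFrame(
            self.normalized if normalized else self.raw,
            columns=self.parameter_names,
        )


def _as_matrix(individuals, etype: str) -> ParameterMatrix:
    if isinstance(individuals, ParameterMatrix):
        return individuals
    rows, run_ids = [], []
    names = None
    for ind in individuals:
        params = ind.params if hasattr(ind, "params") else dict(ind)
        if names is None:
            names = list(params)
        rows.append([params[k] for k in names])
        run_ids.append(getattr(ind, "index", None))
    return ParameterMatrix(etype=etype, parameter_names=names, raw=np.array(rows),
                           run_ids=run_ids)


def normalize_parameter_matrix(individuals, etype: str = "") -> ParameterMatrix:
    """Normalize each parameter column to its maximum across all individuals
    of the e-type (all-zero columns flagged, not divided)."""
    m = _as_matrix(individuals, etype)
    if m.n < 1:
        raise ValueError("need at least one individual")
    col_max = np.abs(m.raw).max(axis=0)
    zero = col_max == 0
    safe = np.where(zero, 1.0, col_max)
    m.normalized = m.raw / safe
    m.column_max = col_max
    m.zero_columns = [n for n, z in zip(m.parameter_names, zero) if z]
    return m


def stability_analysis(matrix: ParameterMatrix, sd_threshold: float = STABILITY_SD) -> list[str]:
    """Parameters whose normalized column has sample sd strictly below the
    threshold — the conductances an e-type must keep tightly constrained."""
    if matrix.n < 2:
        raise ValueError("stability needs >=2 individuals")
    if matrix.normalized is None:
        matrix = normalize_parameter_matrix(matrix, matrix.etype)
    sds = matrix.normalized.std(axis=0, ddof=1)
    return [n for n, s in zip(matrix.parameter_names, sds) if s < sd_threshold]


@dataclass
class DegeneracyReport:
    """Bundled results of the analysis battery over one e-type's individuals."""

    etype: str
    matrix: ParameterMatrix
    stable_parameters: list[str]
    correlations: pd.DataFrame
    proportions: pd.DataFrame
    etype_flags: pd.DataFrame | None = None
    transfer: pd.DataFrame | None = None
    io: pd.DataFrame | None = None
    bap: list[dict] | None = None

    def to_json_dict(self) -> dict:
        out = {
            "etype": self.etype,
            "n_individuals": self.matrix.n,
            "stable_parameters": self.stable_parameters,
            "correlations": self.correlations.to_dict(orient="records"),
            "proportions": self.proportions.to_dict(orient="records"),
        }
        for name in ("etype_flags", "transfer", "io"):
            table = getattr(self, name)
            if table is not None:
                out[name] = table.to_dict(orient="records")
        if self.bap is not None:
            out["bap"] = self.bap
        return out


def analyze_individuals(individuals, etype: str) -> DegeneracyReport:
    """Run the core parameter-level battery (normalization, stability,
    correlations, proportions) over pooled individuals of one e-type."""
    matrix = normalize_parameter_matrix(individuals, etype)
    return DegeneracyReport(
        etype=etype,
        matrix=matrix,
        stable_parameters=stability_analysis(matrix),
        correlations=pairwise_spearman(matrix),
        proportions=channel_proportions(matrix),
    )


# ---------------------------------------------------------------------------
# Spearman correlations


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 8).

    Enumerates every permutation of one variable's ranks; only the rank
    cross-product varies, so batches are evaluated as a single matrix
    product."""
    n = x.size
    rx = stats.rankdata(x) - (n + 1) / 2.0
    ry = stats.rankdata(y) - (n + 1) / 2.0
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    count = total = 0
    thresh = abs(rho_obs) - 1e-12
    batch: list = []

    def flush():
        nonlocal count, total
        if not batch:
            return
        P = np.array(batch)
        r = (ry[P] * rx).sum(axis=1) / denom
        count += int((np.abs(r) >= thresh).sum())
        total += len(batch)
        batch.clear()

    for perm in itertools.permutations(range(n)):
        batch.append(perm)
        if len(batch) == 20000:
            flush()
    flush()
    return count / total


def spearman_with_p(x, y, exact_n: int = 8) -> tuple[float, float]:
    """Tie-corrected Spearman rho with exact permutation p for small n
    (<= ``exact_n``), t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    rho, p_t = stats.spearmanr(x, y)
    if x.size <= exact_n:
        return float(rho), float(_exact_spearman_p(x, y, rho))
    return float(rho), float(p_t)


def pairwise_spearman(
    matrix: ParameterMatrix,
    rho_threshold: float = RHO_THRESHOLD,
    alpha: float = ALPHA,
    reduce: bool = True,
) -> pd.DataFrame:
    """Spearman rho and p for every parameter pair, flagged where
    |rho| > threshold and raw p < alpha.

    Benjamini–Hochberg adjusted p-values are reported alongside, but flags
    use the raw p to mirror the printed tables.  With ``reduce`` the table
    keeps only parameters with at least one flag.  Constant columns yield
    undefined (NaN) rho and are never flagged.
    """
    if matrix.n < 5:
        raise ValueError("pairwise correlations need >=5 individuals")
    if matrix.normalized is None:
        matrix = normalize_parameter_matrix(matrix, matrix.etype)
    names = matrix.parameter_names
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rho, p = spearman_with_p(matrix.raw[:, i], matrix.raw[:, j])
        flagged = bool(np.isfinite(rho) and abs(rho) > rho_threshold
                       and np.isfinite(p) and p < alpha)
        rows.append({"param_a": names[i], "param_b": names[j],
                     "rho": rho, "p": p, "flagged": flagged})
    table = pd.DataFrame(rows)
    finite = table["p"].notna()
    table["p_adj"] = np.nan
    if finite.any():
        table.loc[finite, "p_adj"] = stats.false_discovery_control(
            table.loc[finite, "p"], method="bh"
        )
    if reduce:
        keep = set(table.loc[table.flagged, "param_a"]) | set(
            table.loc[table.flagged, "param_b"]
        )
        table = table[table.param_a.isin(keep) & table.param_b.isin(keep)]
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Channel proportions


def channel_proportions(individuals, etype: str = "", by: str = "parameter") -> pd.DataFrame:
    """Proportion of each conductance in the total average peak conductance.

    Means are taken over individuals on raw gbar values (S/cm², no membrane
    area weighting); fractions are means divided by the summed means, so they
    add to 1.  ``by="channel"`` additionally pools compartment classes of the
    same channel.
    """
    m = _as_matrix(individuals, etype)
    cond = [n for n in m.parameter_names if n.startswith("g") and "bar" in n]
    if not cond:
        raise ValueError("no conductance parameters in matrix")
    idx = [m.parameter_names.index(n) for n in cond]
    means = m.raw[:, idx].mean(axis=0)
    if by == "channel":
        pooled: dict[str, float] = {}
        for n, mu in zip(cond, means):
            key = n.split("bar")[0][1:]  # strip leading g and trailing 'bar c'
            pooled[key] = pooled.get(key, 0.0) + mu
        cond, means = list(pooled), np.array(list(pooled.values()))
    total = means.sum()
    if total == 0:
        raise ValueError("all mean conductances are zero; proportions undefined")
    return pd.DataFrame({"parameter": cond, "mean_gbar": means,
                         "fraction": means / total})


# ---------------------------------------------------------------------------
# E-type comparisons (Kruskal–Wallis + Dunn)


def dunn_test(groups: dict[str, np.ndarray], alpha: float = ALPHA,
              adjust: str | None = None) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks after a Kruskal–Wallis test.

    Uses the tie-corrected Dunn statistic; two-sided normal p-values,
    optionally Holm-adjusted (default none, mirroring a plain p<0.05 rule).
    Direction reports whether the first group's average is lower or higher.
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    N = values.size
    ranks = stats.rankdata(values)
    rbar = {g: ranks[labels == g].mean() for g in names}
    ns = {g: (labels == g).sum() for g in names}
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1))
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / ns[a] + 1.0 / ns[b]))
        z = (rbar[a] - rbar[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        mean_a = np.mean(groups[a])
        mean_b = np.mean(groups[b])
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p,
                     "direction": "lower" if mean_a < mean_b else
                                  ("higher" if mean_a > mean_b else "equal")})
    table = pd.DataFrame(rows)
    if adjust == "holm":
        order = np.argsort(table["p"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m - rank_i) * table["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p"] = adj
    table["flagged"] = table["p"] < alpha
    return table


def etype_comparison(samples: dict[str, dict[str, np.ndarray]],
                     alpha: float = ALPHA) -> pd.DataFrame:
    """Per-parameter comparison of e-type populations.

    ``samples`` maps e-type -> parameter -> values.  For each parameter
    present in >=2 e-types with >=3 samples each: Kruskal–Wallis across
    e-types; if significant, Dunn's pairwise tests with direction.  Identical
    samples produce no flags.
    """
    etypes = list(samples)
    if len(etypes) < 2:
        raise ValueError("need >=2 e-types")
    params = sorted(set().union(*(samples[e].keys() for e in etypes)))
    rows = []
    for param in params:
        groups = {e: np.asarray(samples[e][param], dtype=float)
                  for e in etypes if param in samples[e]}
        groups = {e: v for e, v in groups.items() if v.size >= 3}
        if len(groups) < 2:
            continue
        pooled = np.concatenate(list(groups.values()))
        if np.all(pooled == pooled[0]):
            continue  # identical everywhere: nothing to test
        H, p_kw = stats.kruskal(*groups.values())
        if p_kw >= alpha:
            continue
        dunn = dunn_test(groups, alpha=alpha)
        for _, r in dunn[dunn.flagged].iterrows():
            rows.append({"parameter": param, "etype_a": r.group_a,
                         "etype_b": r.group_b, "direction": r.direction,
                         "p": r.p, "kruskal_p": p_kw})
    return pd.DataFrame(rows, columns=["parameter", "etype_a", "etype_b",
                                       "direction", "p", "kruskal_p"])


# ---------------------------------------------------------------------------
# Morphology transfer


def morphology_transfer(
    best_params: dict[str, float],
    morphologies: list[Morphology],
    objectives: ObjectiveSet,
    template,
    per_morphology_max_total: dict[str, float] | None = None,
    evaluator_factory=None,
) -> pd.DataFrame:
    """Evaluate one fixed conductance set on a list of morphologies.

    Reports the total score per morphology, a within-range flag when the
    score does not exceed that morphology's own maximum accepted total, and
    Spearman correlations of the total against soma area, total volume and
    section count.
    """
    from .objectives import ModelEvaluator  # local import avoids cycle at init

    if len(morphologies) < 2:
        raise ValueError("transfer needs >=2 morphologies")
    rows = []
    for morph in morphologies:
        ev = (evaluator_factory(morph) if evaluator_factory is not None
              else ModelEvaluator(template, objectives, morphology=morph))
        try:
            rep = ev.evaluate(best_params)
            total = rep.total
            failed = rep.failed
        except Exception:  # pragma: no cover - evaluator absorbs failures
            total, failed = math.inf, True
        mm = morphometrics(morph)
        row = {"morphology": morph.identifier, "total": total, "failed": failed,
               "soma_area": mm.soma_area, "total_volume": mm.total_volume,
               "n_sections": mm.n_sections}
        if per_morphology_max_total is not None:
            limit = per_morphology_max_total.get(morph.identifier, np.nan)
            row["within_range"] = bool(total <= limit) if np.isfinite(limit) else False
        rows.append(row)
    table = pd.DataFrame(rows)
    for metric in ("soma_area", "total_volume", "n_sections"):
        rho, p = spearman_with_p(table["total"], table[metric])
        table.attrs[f"spearman_{metric}"] = (rho, p)
    return table


# ---------------------------------------------------------------------------
# I/O curves and bAP attenuation


def io_curves(
    model_counts: dict[float, np.ndarray],
    reference_counts: dict[float, np.ndarray],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Spike-count distributions per amplitude with two-sided Mann–Whitney U
    comparisons of model vs reference; amplitudes with <3 samples on either
    side are reported untested."""
    amps = sorted(set(model_counts) & set(reference_counts))
    if not amps:
        raise ValueError("no overlapping amplitudes")
    rows = []
    for a in amps:
        xm = np.asarray(model_counts[a], dtype=float)
        xr = np.asarray(reference_counts[a], dtype=float)
        row = {"amplitude": a, "model_mean": xm.mean(), "reference_mean": xr.mean(),
               "n_model": xm.size, "n_reference": xr.size}
        if xm.size >= 3 and xr.size >= 3:
            U, p = stats.mannwhitneyu(xm, xr, alternative="two-sided")
            row.update({"U": U, "p": p, "tested": True, "different": bool(p < alpha)})
        else:
            warnings.warn(f"amplitude {a}: <3 samples on one side; test skipped")
            row.update({"U": np.nan, "p": np.nan, "tested": False, "different": False})
        rows.append(row)
    return pd.DataFrame(rows)


def bap_attenuation_analysis(
    profile: list[tuple[float, float]],
    strong_threshold: float = 0.3,
    weak_threshold: float = 0.5,
) -> dict:
    """Classify a backpropagating-AP amplitude profile.

    The ratio of the most distal amplitude to the somatic/most proximal one
    determines the class: < ``strong_threshold`` → strong-attenuating,
    >= ``weak_threshold`` → weak-attenuating, otherwise intermediate —
    the observed dichotomy with few cases in between.
    """
    if len(profile) < 3:
        raise ValueError("profile needs >=3 distances")
    profile = sorted(profile)
    distances = [d for d, _ in profile]
    if max(distances) <= 150.0:
        raise ValueError("profile must extend beyond 150 µm from the soma")
    somatic = profile[0][1]
    if somatic <= 0:
        raise ValueError("missing somatic/proximal reference amplitude")
    ratio = profile[-1][1] / somatic
    if ratio < strong_threshold:
        klass = "strong-attenuating"
    elif ratio >= weak_threshold:
        klass = "weak-attenuating"
    else:
        klass = "intermediate"
    return {"ratio": float(ratio), "class": klass,
            "distal_distance": float(profile[-1][0])}
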