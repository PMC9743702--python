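"""Fitting the scanning-model probabilities to reporter fluorescence data.

The observed side is a vector of Solo-normalised GFP intensities for Duo
reporters (one value per dATG position); the simulated side is the model's
predicted normalised expression for the same layouts.  The objective is the
residual sum of squares (RSS).  Optimisation follows a two-stage scheme: a
coarse grid screen over all three probabilities, then greedy
sequential-update chains that propose one parameter at a time from a
uniform window centred on the current value and accept only proposals that
reduce the RSS.  Although chains of this kind are often loosely called
MCMC, the acceptance rule makes this a stochastic hill-climb; it is
implemented exactly as such.
"""

from __future__ import annotations

import itertools
import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ratchet_core import (
    ExactScanResult,
    MrnaLayout,
    ScanParameters,
    exact_recognition_probabilities,
    simulate_ensemble,
    solo_layout,
)

__all__ = [
    "DEFAULT_GRID",
    "ChainConfig",
    "ChainResult",
    "GridScreenResult",
    "rss",
    "predicted_expression",
    "grid_screen",
    "run_chain",
    "run_chains",
    "summarize_chains",
    "fit_context_leakage",
    "predict_nmd_null",
    "load_observations",
    "observed_vector",
]

#: Grid values screened for each of the three probabilities (10^3 sets).
DEFAULT_GRID: tuple[float, ...] = (0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)

_PARAM_NAMES = ("p_pawl", "p_leakage", "p_nmd")


def rss(simulated: np.ndarray, observed: np.ndarray) -> float:
    """Residual sum of squares between two Solo-normalised expression vectors."""
    simulated = np.asarray(simulated, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if simulated.shape != observed.shape:
        raise ValueError(f"length mismatch: {simulated.shape} vs {observed.shape}")
    if np.isnan(simulated).any() or np.isnan(observed).any():
        raise ValueError("NaN entries in expression vectors")
    return float(np.sum((simulated - observed) ** 2))


def predicted_expression(
    solo: MrnaLayout,
    duos: Sequence[MrnaLayout],
    params: ScanParameters,
    sims_per_variant: int = 100,
    rng: np.random.Generator | None = None,
    use_oracle: bool = False,
) -> np.ndarray:
    """Model expression for each Duo layout, normalised by the Solo layout.

    With ``use_oracle=True`` expression is computed from the exact
    absorbing-chain solve (deterministic, no Monte-Carlo noise); otherwise
    from ``sims_per_variant`` stochastic trajectories per layout.
    """

    if use_oracle:
        solo_expr = exact_recognition_probabilities(solo, params).expression
        expr = np.array(
            [exact_recognition_probabilities(d, params).expression for d in duos]
        )
    else:
        if rng is None:
            raise ValueError("simulation mode requires an rng")
        solo_expr = simulate_ensemble(solo, params, sims_per_variant, rng).expression
        expr = np.array(
            [simulate_ensemble(d, params, sims_per_variant, rng).expression for d in duos]
        )
    if solo_expr <= 0:
        raise ZeroDivisionError("Solo expression is zero under these parameters")
    return expr / solo_expr


@dataclass
class GridScreenResult:
    table: pd.DataFrame  # all grid sets with their RSS, sorted ascending
    top_sets: list[ScanParameters]
    start: ScanParameters  # per-parameter median of the top sets


def grid_screen(
    observed: np.ndarray,
    solo: MrnaLayout,
    duos: Sequence[MrnaLayout],
    grid: Mapping[str, Sequence[float]] | None = None,
    sims_per_set: int = 100,
    rng: np.random.Generator | None = None,
    top_k: int = 10,
    use_oracle: bool = False,
) -> GridScreenResult:
    """Screen a parameter grid and return chain start values.

    Evaluates the RSS for every combination of grid values (default: the
    ten canonical values per parameter, 1000 sets), keeps the ``top_k``
    lowest-RSS sets and takes the per-parameter median among them as the
    start point for the greedy chains.
    """

    observed = np.asarray(observed, dtype=float)
    if observed.size == 0:
        raise ValueError("empty observation vector")
    if grid is None:
        grid = {name: DEFAULT_GRID for name in _PARAM_NAMES}
    combos = list(
        itertools.product(grid["p_pawl"], grid["p_leakage"], grid["p_nmd"])
    )
    records = []
    for p_pawl, p_leakage, p_nmd in combos:
        params = ScanParameters(p_pawl, p_leakage, p_nmd)
        sim = predicted_expression(solo, duos, params, sims_per_set, rng, use_oracle)
        records.append((p_pawl, p_leakage, p_nmd, rss(sim, observed)))
    table = pd.DataFrame(records, columns=[*_PARAM_NAMES, "rss"]).sort_values(
        "rss", kind="stable", ignore_index=True
    )
    top = table.head(top_k)
    top_sets = [
        ScanParameters(r.p_pawl, r.p_leakage, r.p_nmd) for r in top.itertuples()
    ]
    start = ScanParameters(
        *(float(top[name].median()) for name in _PARAM_NAMES)
    )
    return GridScreenResult(table=table, top_sets=top_sets, start=start)


@dataclass(frozen=True)
class ChainConfig:
    """Settings of one greedy optimisation chain.

    ``widths`` are the full widths of the uniform proposal windows,
    roughly twice the parameter spread seen among the best grid-screen
    sets.  Parameters named in ``fixed`` are never updated (used when
    fitting context-specific leakage with the other two probabilities
    pinned).  ``reevaluate_incumbent`` re-simulates the incumbent RSS each
    iteration instead of caching it; off by default, matching a comparison
    of each new RSS against the previous iteration's value.
    """

    n_iterations: int = 300
    widths: Mapping[str, float] = field(
        default_factory=lambda: {"p_pawl": 0.0004, "p_leakage": 0.2, "p_nmd": 0.5}
    )
    update_order: tuple[str, ...] = _PARAM_NAMES
    sims_per_variant: int = 100
    fixed: tuple[str, ...] = ()
    use_oracle: bool = False
    reevaluate_incumbent: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for name in self.update_order:
            if name not in _PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            if name not in self.fixed and self.widths[name] <= 0:
                raise ValueError(f"window width for {name} must be > 0")

    @property
    def free_order(self) -> tuple[str, ...]:
        order = tuple(n for n in self.update_order if n not in self.fixed)
        if not order:
            raise ValueError("all parameters are fixed; nothing to optimise")
        return order


@dataclass
class ChainResult:
    trace: pd.DataFrame  # iteration, p_pawl, p_leakage, p_nmd, rss, accepted
    best_params: ScanParameters
    best_rss: float
    start: ScanParameters


def _propose(current: float, width: float, rng: np.random.Generator) -> float:
    lo = max(0.0, current - width / 2)
    hi = min(1.0, current + width / 2)
    return float(rng.uniform(lo, hi))


def run_chain(
    observed: np.ndarray,
    solo: MrnaLayout,
    duos: Sequence[MrnaLayout],
    start: ScanParameters,
    config: ChainConfig,
    rng: np.random.Generator,
) -> ChainResult:
    """One greedy sequential-update chain.

    Each iteration updates one free parameter (cyclically, in
    ``config.update_order``) with a uniform proposal in a window centred
    on the current value and clipped to [0, 1]; the proposal is accepted
    only if it strictly reduces the RSS.  The full trace and the
    minimum-RSS parameter set are returned.
    """

    observed = np.asarray(observed, dtype=float)
    sim_kwargs = dict(
        sims_per_variant=config.sims_per_variant, rng=rng, use_oracle=config.use_oracle
    )

    def objective(params: ScanParameters) -> float:
        sim = predicted_expression(solo, duos, params, **sim_kwargs)
        return rss(sim, observed)

    current = start
    current_rss = objective(current)
    best, best_rss = current, current_rss
    rows = [(0, *_values(current), current_rss, True)]
    order = config.free_order
    for it in range(1, config.n_iterations + 1):
        name = order[(it - 1) % len(order)]
        proposal = current.replace(**{name: _propose(getattr(current, name), config.widths[name], rng)})
        try:
            new_rss = objective(proposal)
        except Exception as exc:  # pragma: no cover - simulation failure context
            raise RuntimeError(f"simulation failed at chain iteration {it}") from exc
        if config.reevaluate_incumbent:
            current_rss = objective(current)
        accepted = new_rss < current_rss
        if accepted:
            current, current_rss = proposal, new_rss
            if new_rss < best_rss:
                best, best_rss = proposal, new_rss
        rows.append((it, *_values(current), current_rss, accepted))
    trace = pd.DataFrame(
        rows, columns=["iteration", *_PARAM_NAMES, "rss", "accepted"]
    )
    return ChainResult(trace=trace, best_params=best, best_rss=best_rss, start=start)


def _values(params: ScanParameters) -> tuple[float, float, float]:
    return params.p_pawl, params.p_leakage, params.p_nmd


def run_chains(
    observed: np.ndarray,
    solo: MrnaLayout,
    duos: Sequence[MrnaLayout],
    start: ScanParameters,
    config: ChainConfig,
    n_chains: int,
    seed: int | np.random.SeedSequence,
) -> list[ChainResult]:
    """Run independent chains from the same start with spawned RNG streams."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [
        run_chain(observed, solo, duos, start, config, np.random.default_rng(child))
        for child in ss.spawn(n_chains)
    ]


def summarize_chains(results: Sequence[ChainResult]) -> pd.DataFrame:
    """Mean and standard error of each parameter over the chains' best sets."""
    if len(results) < 2:
        raise ValueError("need at least 2 chains to summarise")
    best = pd.DataFrame([_values(r.best_params) for r in results], columns=_PARAM_NAMES)
    return pd.DataFrame(
        {"mean": best.mean(), "se": best.std(ddof=1) / np.sqrt(len(results))}
    )


def fit_context_leakage(
    solo_observed: Mapping[str, float],
    p_pawl: float,
    p_nmd: float,
    reference_leakage: float,
    solo: MrnaLayout | None = None,
    config: ChainConfig | None = None,
    n_chains: int = 30,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Fit a per-context single-scan leakage from Solo reporter intensities.

    ``solo_observed`` maps a -3 context (e.g. ``"A"``) to the mean GFP of
    Solo reporters in that context, normalised by the overall (N-context)
    Solo mean.  ``p_pawl`` and ``p_nmd`` stay pinned at their globally
    fitted values while short chains optimise the leakage alone; the
    simulated counterpart of each observation is the Solo expression under
    the candidate leakage divided by the Solo expression under
    ``reference_leakage`` (the global fit, representing the N context).

    Returns one row per context with the mean fitted leakage, its SE and
    the implied net leakage (exact solve).
    """

    if solo is None:
        solo = solo_layout()
    if config is None:
        config = ChainConfig(n_iterations=100, fixed=("p_pawl", "p_nmd"))
    elif set(config.fixed) != {"p_pawl", "p_nmd"}:
        raise ValueError("context fit requires p_pawl and p_nmd to be fixed")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)

    ref_params = ScanParameters(p_pawl, reference_leakage, p_nmd)
    rows = []
    for context, child in zip(sorted(solo_observed), ss.spawn(len(solo_observed))):
        obs = np.array([solo_observed[context]])
        start = ScanParameters(p_pawl, reference_leakage, p_nmd)
        # Normalising layout is the Solo at the reference leakage: encode it
        # as the "solo" argument and the context-specific Solo as the target.
        results = [
            run_chain(obs, _ref_solo(solo, reference_leakage), [solo], start, config,
                      np.random.default_rng(grandchild))
            for grandchild in child.spawn(n_chains)
        ]
        fitted = [r.best_params.p_leakage for r in results]
        mean_leak = float(np.mean(fitted))
        se = float(np.std(fitted, ddof=1) / np.sqrt(len(fitted))) if len(fitted) > 1 else 0.0
        net = exact_recognition_probabilities(
            solo, ScanParameters(p_pawl, mean_leak, p_nmd)
        ).net_leakage
        rows.append((context, mean_leak, se, net))
    return pd.DataFrame(
        rows, columns=["context", "p_leakage_mean", "p_leakage_se", "net_leakage"]
    ).set_index("context")


def _ref_solo(solo: MrnaLayout, reference_leakage: float) -> MrnaLayout:
    """A copy of the Solo layout whose site leakage is pinned to the reference."""
    site = solo.sites[0]
    from dataclasses import replace as _replace

    return _replace(
        solo,
        sites=(
            _replace(site, leakage_override=reference_leakage),
        ),
        label=f"{solo.label or 'Solo'}(reference)",
    )


def predict_nmd_null(
    solo: MrnaLayout,
    duos: Sequence[MrnaLayout],
    params: ScanParameters,
    n_reps: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Re-predict expression with the NMD pathway switched off.

    Sets ``p_nmd = 0`` so that the predicted mRNA level is 1 for every
    variant and expression equals the functional-initiation fraction
    alone; mimics measurements in an NMD-deficient background.
    """

    null = params.replace(p_nmd=0.0)
    rows = []
    for layout in [solo, *duos]:
        if n_reps is None:
            res = exact_recognition_probabilities(layout, null)
            expr, mrna = res.expression, res.mrna
        else:
            if rng is None:
                raise ValueError("simulation mode requires an rng")
            summ = simulate_ensemble(layout, null, n_reps, rng)
            expr, mrna = summ.expression, summ.mrna
        rows.append((layout.label, expr, mrna))
    df = pd.DataFrame(rows, columns=["label", "expression", "mrna"])
    solo_expr = df["expression"].iloc[0]
    df["expression_norm"] = df["expression"] / solo_expr
    return df


# ---------------------------------------------------------------------------
# observation tables


def load_observations(path: str | Path) -> pd.DataFrame:
    """Read a TSV of observations (label, position, frame, context, gfp_norm)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"label", "position", "frame", "context", "gfp_norm"} - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    if (df["gfp_norm"] < 0).any():
        raise ValueError("normalised GFP must be non-negative")
    return df


def observed_vector(
    observations: pd.DataFrame,
    positions: Sequence[int],
    frame: str = "out",
    context: str = "N",
) -> np.ndarray:
    """Per-position mean normalised GFP aligned with a Duo layout list.

    By default selects out-of-frame observations (``frame`` column values
    other than 0) in the N context, mirroring the subset used for the RSS.
    """

    df = observations
    if context != "any":
        df = df[df["context"] == context]
    if frame == "out":
        df = df[df["frame"] != 0]
    elif frame == "in":
        df = df[df["frame"] == 0]
    means = df.groupby("position")["gfp_norm"].mean()
    out = []
    for p in positions:
        if p not in means.index:
            raise ValueError(f"no observation for position +{p}")
        out.append(means.loc[p])
    return np.array(out)


def fit_report(
    screen: GridScreenResult,
    results: Sequence[ChainResult],
    path: str | Path | None = None,
) -> dict:
    """Assemble (and optionally write) a JSON-serialisable fit report."""
    summary = summarize_chains(results)
    report = {
        "start": screen.start.as_dict(),
        "grid_top10": [p.as_dict() for p in screen.top_sets],
        "best_per_chain": [
            {**r.best_params.as_dict(), "rss": r.best_rss} for r in results
        ],
        "mean": summary["mean"].to_dict(),
        "se": summary["se"].to_dict(),
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=1))
    return report
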