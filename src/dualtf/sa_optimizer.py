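"""Simulated-annealing fitting of the thermodynamic model.

The objective is the mean Pearson correlation between observed and predicted
expression over the CRMs in the training set. Annealing uses a geometric
cooling schedule and Metropolis acceptance on the negative objective. Repeats
run on independent derived random streams, so results are reproducible for a
given master seed and adding repeats never discards earlier ones.

The hot inner loop runs on a pre-compiled representation of the dataset
(site/concentration arrays and quench masks per CRM); ``objective`` is the
plain reference implementation built on :func:`dualtf.thermo_model.predict_expression`
and the two must agree to float precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import ProfileSet
from .site_scanner import TFBS
from .thermo_model import (
    ACT,
    REP,
    Configuration,
    DEFAULT_QUENCH_DISTANCE,
    ExpressionProfile,
    ModelParams,
    pearson_cc,
    predict_expression,
)

_REPEAT_SALT = 0x5A17  # keeps repeat streams distinct from other derived seeds


@dataclass(frozen=True)
class SASchedule:
    """Geometric-cooling annealing schedule: ``T_k = T0 * alpha**k``."""

    T0: float = 0.05
    alpha: float = 0.995
    iterations: int = 1000
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")


@dataclass
class Dataset:
    """Everything needed to fit one or more CRMs.

    ``sites`` maps CRM id to its predicted binding sites, ``concentrations``
    holds one track per TF and ``observed`` one track per CRM, all on a shared
    axis.
    """

    tf_names: tuple[str, ...]
    crm_ids: tuple[str, ...]
    sites: dict[str, list[TFBS]]
    concentrations: ProfileSet
    observed: ProfileSet

    def __post_init__(self) -> None:
        if not self.crm_ids:
            raise ValueError("dataset must contain at least one CRM")
        for crm in self.crm_ids:
            if crm not in self.observed:
                raise ValueError(f"no observed profile for CRM {crm!r}")
            for s in self.sites.get(crm, []):
                if s.tf not in self.tf_names:
                    raise ValueError(f"site TF {s.tf!r} not in panel")
        for tf in self.tf_names:
            if tf not in self.concentrations:
                raise ValueError(f"no concentration track for TF {tf!r}")

    @property
    def n_tfs(self) -> int:
        return len(self.tf_names)

    def subset(self, crm_ids: Sequence[str]) -> "Dataset":
        return Dataset(
            tf_names=self.tf_names,
            crm_ids=tuple(crm_ids),
            sites={c: self.sites.get(c, []) for c in crm_ids},
            concentrations=self.concentrations,
            observed=self.observed,
        )


@dataclass
class FitResult:
    best_params: ModelParams
    mean_cc: float
    se_cc: float
    per_crm_cc: dict[str, float]
    trace: list[float]  # best objective per repeat
    history: list[np.ndarray] | None = None  # best-so-far curves when recorded


# ---------------------------------------------------------------------------
# Free-parameter space

#: (lo, hi, scale) default bounds per parameter kind.
DEFAULT_BOUNDS = {
    "K": (1e-2, 1e2, "log"),
    "E_act": (1e-3, 10.0, "log"),
    "E_rep": (1e-3, 1.0, "log"),
    "G0": (-5.0, 5.0, "lin"),
    "R0": (0.1, 10.0, "log"),
}


@dataclass(frozen=True)
class _ParamEntry:
    kind: str  # K | E_act | E_rep | G0 | R0
    tf_index: int  # -1 for globals
    lo: float
    hi: float
    scale: str  # log | lin


class ParamSpace:
    """Maps the SA search vector onto :class:`ModelParams`.

    Free entries: one ``K`` per TF; for each TF, the effectiveness constants
    of every role it takes somewhere in the training set (one for fixed-role
    TFs, two for dual TFs); plus the global ``G0`` and ``R0``. The quench
    distance ``d`` is fixed, not fitted.
    """

    def __init__(
        self,
        tf_names: Sequence[str],
        roles_per_crm: Mapping[str, Configuration],
        dual_tfs: frozenset[str] = frozenset(),
        bounds: Mapping[str, tuple] | None = None,
        d: float = DEFAULT_QUENCH_DISTANCE,
    ) -> None:
        self.tf_names = tuple(tf_names)
        self.dual_tfs = frozenset(dual_tfs)
        self.d = d
        b = dict(DEFAULT_BOUNDS)
        if bounds:
            b.update(bounds)
        n = len(self.tf_names)
        roles_seen: list[set[int]] = [set() for _ in range(n)]
        for cfg in roles_per_crm.values():
            if cfg.n != n:
                raise ValueError("configuration size does not match panel")
            for i, r in enumerate(cfg.roles):
                roles_seen[i].add(r)
        for i, seen in enumerate(roles_seen):
            if len(seen) > 1 and self.tf_names[i] not in self.dual_tfs:
                raise ValueError(
                    f"TF {self.tf_names[i]!r} takes both roles but is not declared dual"
                )
        self.entries: list[_ParamEntry] = []
        for i in range(n):
            self.entries.append(_ParamEntry("K", i, *b["K"]))
        for i in range(n):
            name = self.tf_names[i]
            acts = ACT in roles_seen[i] or not roles_seen[i]
            reps = REP in roles_seen[i]
            if name in self.dual_tfs:
                acts = reps = True
            if acts:
                self.entries.append(_ParamEntry("E_act", i, *b["E_act"]))
            if reps:
                self.entries.append(_ParamEntry("E_rep", i, *b["E_rep"]))
        self.entries.append(_ParamEntry("G0", -1, *b["G0"]))
        self.entries.append(_ParamEntry("R0", -1, *b["R0"]))

    @property
    def size(self) -> int:
        return len(self.entries)

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        x = np.empty(self.size)
        for j, e in enumerate(self.entries):
            if e.scale == "log":
                x[j] = np.exp(rng.uniform(np.log(e.lo), np.log(e.hi)))
            else:
                x[j] = rng.uniform(e.lo, e.hi)
        return x

    def propose(self, x: np.ndarray, rng: np.random.Generator, sigma: float = 0.2) -> np.ndarray:
        """Perturb one uniformly chosen entry; reflect at the bounds.

        Steps are a 70/30 mixture of a local kick and one five times wider,
        which lets the chain hop between occupancy regimes that a purely
        local proposal crosses too slowly.
        """
        y = x.copy()
        j = int(rng.integers(self.size))
        e = self.entries[j]
        if rng.random() >= 0.7:
            sigma = 5.0 * sigma
        if e.scale == "log":
            v = np.log(y[j]) + rng.normal(0.0, sigma)
            lo, hi = np.log(e.lo), np.log(e.hi)
            v = _reflect(v, lo, hi)
            y[j] = np.exp(v)
        else:
            v = _reflect(y[j] + rng.normal(0.0, sigma), e.lo, e.hi)
            y[j] = v
        return y

    def to_params(self, x: np.ndarray) -> ModelParams:
        n = len(self.tf_names)
        K = np.empty(n)
        E_act = np.zeros(n)
        E_rep = np.zeros(n)
        G0 = R0 = 0.0
        for j, e in enumerate(self.entries):
            if e.kind == "K":
                K[e.tf_index] = x[j]
            elif e.kind == "E_act":
                E_act[e.tf_index] = x[j]
            elif e.kind == "E_rep":
                E_rep[e.tf_index] = x[j]
            elif e.kind == "G0":
                G0 = float(x[j])
            else:
                R0 = float(x[j])
        return ModelParams(
            names=self.tf_names, K=K, E_act=E_act, E_rep=E_rep,
            G0=G0, R0=R0, d=self.d, dual_tfs=self.dual_tfs,
        )


def _reflect(v: float, lo: float, hi: float) -> float:
    width = hi - lo
    if width <= 0:
        return lo
    v = (v - lo) % (2 * width)
    if v > width:
        v = 2 * width - v
    return lo + v


# ---------------------------------------------------------------------------
# Objective

def objective(
    params: ModelParams,
    dataset: Dataset,
    roles_per_crm: Mapping[str, Configuration],
) -> float:
    """Mean over CRMs of the Pearson CC between observed and predicted profiles."""
    ccs = []
    for crm in dataset.crm_ids:
        pred = predict_expression(
            dataset.sites.get(crm, []), dataset.concentrations, params, roles_per_crm[crm]
        )
        obs = ExpressionProfile(dataset.observed.axis, dataset.observed[crm])
        ccs.append(pearson_cc(obs, pred))
    return float(np.mean(ccs))


class _CompiledCRM:
    """Arrays for one CRM under a fixed role configuration."""

    __slots__ = ("tfa", "tfr", "Aq", "Rq", "Va", "Vr", "mask", "obs_z", "obs_const", "n_pos")

    def __init__(self, sites: list[TFBS], conc: ProfileSet, tf_names: tuple[str, ...],
                 cfg: Configuration, d: float, observed: np.ndarray) -> None:
        idx = {name: i for i, name in enumerate(tf_names)}
        tf_i = np.array([idx[s.tf] for s in sites], dtype=int)
        q = np.array([s.q for s in sites])
        centers = np.array([s.center for s in sites])
        roles = np.array([cfg.role_of(i) for i in tf_i], dtype=int) if sites else np.empty(0, int)
        V = (
            np.stack([conc[s.tf] for s in sites])
            if sites
            else np.empty((0, conc.axis.size))
        )
        a = roles == ACT
        r = roles == REP
        self.tfa = tf_i[a]
        self.tfr = tf_i[r]
        self.Aq = q[a][:, None]
        self.Rq = q[r][:, None]
        self.Va = V[a]
        self.Vr = V[r]
        self.mask = (
            np.abs(centers[a][:, None] - centers[r][None, :]) <= d
        ).astype(float)
        self.n_pos = conc.axis.size
        std = observed.std()
        self.obs_const = std == 0.0
        self.obs_z = (
            np.zeros_like(observed)
            if self.obs_const
            else (observed - observed.mean()) / (std * np.sqrt(observed.size))
        )

    def cc(self, params: ModelParams) -> float:
        if self.obs_const:
            return 0.0
        if self.tfa.size:
            xa = params.K[self.tfa, None] * self.Va * self.Aq
            fa = xa / (1.0 + xa)
            A = params.E_act[self.tfa, None] * fa
            if self.tfr.size:
                xr = params.K[self.tfr, None] * self.Vr * self.Rq
                fr = xr / (1.0 + xr)
                A = A * np.exp(self.mask @ np.log(1.0 - params.E_rep[self.tfr, None] * fr))
            sigma = A.sum(axis=0)
        else:
            sigma = np.zeros(self.n_pos)
        pred = 1.0 / (1.0 + np.exp(-(sigma - params.G0)))  # R0 cancels in the CC
        std = pred.std()
        if std == 0.0:
            return 0.0
        pred_z = (pred - pred.mean()) / (std * np.sqrt(pred.size))
        return float(np.clip(pred_z @ self.obs_z, -1.0, 1.0))


def compile_dataset(
    dataset: Dataset,
    roles_per_crm: Mapping[str, Configuration],
    d: float,
) -> list[_CompiledCRM]:
    return [
        _CompiledCRM(
            dataset.sites.get(crm, []),
            dataset.concentrations,
            dataset.tf_names,
            roles_per_crm[crm],
            d,
            dataset.observed[crm],
        )
        for crm in dataset.crm_ids
    ]


def compiled_objective(compiled: list[_CompiledCRM], params: ModelParams) -> float:
    return float(np.mean([c.cc(params) for c in compiled]))


# ---------------------------------------------------------------------------
# Annealing

def repeat_seed(master: int, repeat: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([_REPEAT_SALT, int(master), int(repeat)])


def sa_fit(
    dataset: Dataset,
    roles_per_crm: Mapping[str, Configuration],
    schedule: SASchedule,
    bounds: Mapping[str, tuple] | None = None,
    dual_tfs: frozenset[str] = frozenset(),
    d: float = DEFAULT_QUENCH_DISTANCE,
    proposal_sigma: float = 0.2,
    record_history: bool = False,
) -> FitResult:
    """Fit model parameters by simulated annealing, maximizing the mean CC.

    Each repeat starts from an independent uniform draw over the (log-scaled)
    bounds and runs ``schedule.iterations`` Metropolis steps under geometric
    cooling. The returned parameters are the best found across repeats;
    ``mean_cc``/``se_cc`` summarize the per-repeat best objectives.
    """
    space = ParamSpace(dataset.tf_names, roles_per_crm, dual_tfs, bounds, d)
    compiled = compile_dataset(dataset, roles_per_crm, d)

    best_overall_x: np.ndarray | None = None
    best_overall = -np.inf
    trace: list[float] = []
    history: list[np.ndarray] = []
    for r in range(schedule.repeats):
        rng = np.random.default_rng(repeat_seed(schedule.seed, r))
        x = space.initial(rng)
        fx = compiled_objective(compiled, space.to_params(x))
        best_x, best_f = x, fx
        curve = np.empty(schedule.iterations + 1)
        curve[0] = best_f
        T = schedule.T0
        for k in range(schedule.iterations):
            y = space.propose(x, rng, proposal_sigma)
            fy = compiled_objective(compiled, space.to_params(y))
            # Metropolis on energy = -objective
            if fy >= fx or rng.random() < np.exp((fy - fx) / T):
                x, fx = y, fy
                if fx > best_f:
                    best_x, best_f = x, fx
            curve[k + 1] = best_f
            T *= schedule.alpha
        trace.append(best_f)
        if record_history:
            history.append(curve)
        if best_f > best_overall:
            best_overall, best_overall_x = best_f, best_x

    best_params = space.to_params(best_overall_x)
    per_crm = {
        crm: c.cc(best_params) for crm, c in zip(dataset.crm_ids, compiled)
    }
    trace_arr = np.array(trace)
    se = float(trace_arr.std(ddof=1) / np.sqrt(len(trace))) if len(trace) > 1 else 0.0
    return FitResult(
        best_params=best_params,
        mean_cc=float(trace_arr.mean()),
        se_cc=se,
        per_crm_cc=per_crm,
        trace=trace,
        history=history if record_history else None,
    )
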