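"""TF role inference from a CRM x configuration correlation matrix.

Three methods read the matrix of per-CRM, per-configuration fit correlations:

* ``smallest_optimal`` — take each CRM's optimal configuration(s) and find an
  exact minimum set of configurations covering all CRMs;
* ``best_n`` — exact search for the n configurations that jointly maximize
  the summed CC when every CRM picks its best configuration in the set;
* ``sensitivity`` — per CRM and TF, the largest CC change over all
  configuration pairs differing only in that TF's role.

Per-TF summaries of the three methods are combined by majority vote into
activator ("+"), repressor ("-") or role-switching ("s") labels. The module
also classifies externally computed enrichment p-values into over/under/
background calls with a differential-enrichment rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sa_optimizer import Dataset, SASchedule, sa_fit
from .thermo_model import Configuration, TFPanel, DEFAULT_QUENCH_DISTANCE

ROLE_ACT, ROLE_REP, ROLE_NA = "ACT", "REP", "NA"

#: CC difference below which a TF's role on a CRM is left unassigned.
DEFAULT_EPSILON = 0.1
#: CC difference above which a sensitivity call counts as strong.
DEFAULT_STRONG_THRESHOLD = 0.1
#: Fraction of non-NA calls a role needs to win a per-method summary.
DEFAULT_THETA = 2.0 / 3.0

_MAX_PANEL = 10  # 2**10 configurations; guard for build_cc_matrix
_TIE_TOL = 1e-9


@dataclass
class CCMatrix:
    """Mean fit correlation for every CRM-configuration pair."""

    crms: tuple[str, ...]
    n_tfs: int
    cc: np.ndarray  # |crms| x 2**n_tfs

    def __post_init__(self) -> None:
        self.cc = np.asarray(self.cc, dtype=float)
        expected = (len(self.crms), 2 ** self.n_tfs)
        if self.cc.shape != expected:
            raise ValueError(f"cc matrix must be {expected}, got {self.cc.shape}")
        if not np.all(np.isfinite(self.cc)):
            raise ValueError("cc matrix contains non-finite values")
        if np.any(np.abs(self.cc) > 1 + 1e-9):
            raise ValueError("cc values must lie in [-1, 1]")

    @property
    def n_configs(self) -> int:
        return self.cc.shape[1]


@dataclass(frozen=True)
class RoleCall:
    crm: str
    tf: str
    role: str  # ACT | REP | NA
    strong: bool
    delta_cc: float | None = None

    def __post_init__(self) -> None:
        if self.role not in (ROLE_ACT, ROLE_REP, ROLE_NA):
            raise ValueError(f"bad role {self.role!r}")
        if self.role == ROLE_NA and self.strong:
            raise ValueError("an NA call cannot be strong")


@dataclass
class MethodResult:
    method: str
    chosen_configs: tuple[int, ...]
    per_crm_config: dict[str, int]
    calls: list[RoleCall]

    def calls_for(self, tf: str) -> list[RoleCall]:
        return [c for c in self.calls if c.tf == tf]


@dataclass(frozen=True)
class MethodSummary:
    tf: str
    label: str  # + | - | s
    n_act: int
    n_rep: int
    n_strong_act: int
    n_strong_rep: int


@dataclass
class RoleSummary:
    """Final ensemble role per TF with a strong-call support count."""

    roles: dict[str, str]
    confidence: dict[str, int]


@dataclass(frozen=True)
class EnrichmentCall:
    tf: str
    p_act: float | None
    p_rep: float | None
    status_act: str  # over | under | background | untested
    status_rep: str
    differential: bool

    def __post_init__(self) -> None:
        if self.differential and (self.p_act is None or self.p_rep is None):
            raise ValueError("differential enrichment requires both sets tested")


# ---------------------------------------------------------------------------
# CC matrix construction


def cell_schedule(schedule: SASchedule, crm_index: int, config_index: int) -> SASchedule:
    """Schedule with a per-cell seed derived reproducibly from the master seed."""
    seed = int(
        np.random.SeedSequence(
            entropy=int(schedule.seed), spawn_key=(crm_index, config_index)
        ).generate_state(1)[0]
    )
    return replace(schedule, seed=seed)


def build_cc_matrix(
    dataset: Dataset,
    panel: TFPanel,
    schedule: SASchedule,
    bounds: Mapping[str, tuple] | None = None,
    d: float = DEFAULT_QUENCH_DISTANCE,
) -> CCMatrix:
    """Fit every CRM under every configuration independently.

    Cell ``(c, k)`` holds the mean-over-repeats best CC of annealing CRM ``c``
    alone under configuration ``k``. Deterministic for a fixed master seed.
    """
    n = panel.n
    if n > _MAX_PANEL:
        raise ValueError(
            f"{n} TFs means 2**{n} configurations; restrict the panel to <= {_MAX_PANEL} TFs"
        )
    if tuple(dataset.tf_names) != tuple(panel.names):
        raise ValueError("dataset TF order must match the panel")
    n_cfg = 2 ** n
    cc = np.empty((len(dataset.crm_ids), n_cfg))
    for ci, crm in enumerate(dataset.crm_ids):
        sub = dataset.subset([crm])
        for k in range(n_cfg):
            cfg = Configuration.from_index(k, n)
            fit = sa_fit(sub, {crm: cfg}, cell_schedule(schedule, ci, k), bounds=bounds, d=d)
            cc[ci, k] = fit.mean_cc
    return CCMatrix(tuple(dataset.crm_ids), n, cc)


# ---------------------------------------------------------------------------
# Shared helpers


def _role_pair_indices(n_tfs: int, tf_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Aligned configuration indices with TF ``tf_index`` as activator/repressor.

    Pair ``j`` differs only in that TF's bit, enumerating the other bits in
    increasing order.
    """
    others = [i for i in range(n_tfs) if i != tf_index]
    m = 2 ** (n_tfs - 1)
    act = np.empty(m, dtype=int)
    rep = np.empty(m, dtype=int)
    for j in range(m):
        base = 0
        for b, i in enumerate(others):
            if (j >> b) & 1:
                base |= 1 << i
        act[j] = base | (1 << tf_index)
        rep[j] = base
    return act, rep


def _calls_from_config(
    ccm: CCMatrix, tf_names: Sequence[str], per_crm_config: Mapping[str, int],
    epsilon: float, strong: bool = True,
) -> list[RoleCall]:
    """Per-CRM role calls read off an assigned configuration.

    A TF whose role never moves the CC by ``epsilon`` or more on that CRM (over
    all configuration pairs differing only in that TF) is called NA.
    """
    calls: list[RoleCall] = []
    pairs = [_role_pair_indices(ccm.n_tfs, t) for t in range(len(tf_names))]
    for ci, crm in enumerate(ccm.crms):
        k = per_crm_config[crm]
        for t, tf in enumerate(tf_names):
            act_idx, rep_idx = pairs[t]
            max_delta = float(np.abs(ccm.cc[ci, act_idx] - ccm.cc[ci, rep_idx]).max())
            if max_delta < epsilon:
                calls.append(RoleCall(crm, tf, ROLE_NA, strong=False, delta_cc=max_delta))
            else:
                role = ROLE_ACT if (k >> t) & 1 else ROLE_REP
                calls.append(RoleCall(crm, tf, role, strong=strong, delta_cc=max_delta))
    return calls


def _optimal_sets(ccm: CCMatrix, tie_tol: float) -> list[frozenset[int]]:
    out = []
    for row in ccm.cc:
        out.append(frozenset(np.where(row >= row.max() - tie_tol)[0].tolist()))
    return out


# ---------------------------------------------------------------------------
# SMALLEST-OPTIMAL


def minimum_config_cover(optimal_sets: Sequence[frozenset[int]]) -> tuple[int, ...]:
    """Exact minimum-cardinality set of configurations hitting every CRM's
    optimal set; ties broken toward the lexicographically smallest index set.
    """
    if not optimal_sets:
        return ()
    candidates = sorted(set().union(*optimal_sets))

    # branch and bound for the minimum size
    best_size = len(optimal_sets) + 1

    def bound_search(chosen: list[int], remaining: list[frozenset[int]]) -> None:
        nonlocal best_size
        if not remaining:
            best_size = min(best_size, len(chosen))
            return
        if len(chosen) + 1 >= best_size:
            return
        # branch on the CRM with fewest options
        pivot = min(remaining, key=len)
        for cfg in sorted(pivot):
            nxt = [s for s in remaining if cfg not in s]
            bound_search(chosen + [cfg], nxt)

    bound_search([], list(optimal_sets))

    # lexicographically smallest cover of that size
    for combo in itertools.combinations(candidates, best_size):
        combo_set = set(combo)
        if all(s & combo_set for s in optimal_sets):
            return tuple(combo)
    raise AssertionError("branch-and-bound size has no witness")  # pragma: no cover


def smallest_optimal(
    ccm: CCMatrix,
    tf_names: Sequence[str] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    tie_tol: float = _TIE_TOL,
) -> MethodResult:
    """Cover every CRM with an exact minimum set of row-optimal configurations."""
    tf_names = _default_names(ccm, tf_names)
    optimal = _optimal_sets(ccm, tie_tol)
    chosen = minimum_config_cover(optimal)
    chosen_set = set(chosen)
    per_crm = {
        crm: min(opt & chosen_set) for crm, opt in zip(ccm.crms, optimal)
    }
    calls = _calls_from_config(ccm, tf_names, per_crm, epsilon)
    return MethodResult("smallest_optimal", chosen, per_crm, calls)


# ---------------------------------------------------------------------------
# BEST-N


def best_n(
    ccm: CCMatrix,
    n: int,
    tf_names: Sequence[str] | None = None,
) -> MethodResult:
    """Exact search for the n-configuration subset maximizing the total CC.

    Every CRM is assigned its best configuration inside the subset and all
    role calls are strong. Branch-and-bound with a suffix-max upper bound
    keeps n = 4 over 256 configurations tractable while staying exact; ties
    resolve to the lexicographically smallest configuration-index set.
    """
    if not 1 <= n <= 4:
        raise ValueError("best_n supports n in 1..4")
    tf_names = _default_names(ccm, tf_names)
    cc = ccm.cc
    n_cfg = cc.shape[1]
    n = min(n, n_cfg)

    # suffix_max[j] = per-CRM max over columns j..end
    suffix_max = np.empty((n_cfg + 1, cc.shape[0]))
    suffix_max[n_cfg] = -np.inf
    for j in range(n_cfg - 1, -1, -1):
        suffix_max[j] = np.maximum(suffix_max[j + 1], cc[:, j])

    best_total = -np.inf
    best_combo: tuple[int, ...] = ()

    def search(start: int, chosen: list[int], cur: np.ndarray) -> None:
        nonlocal best_total, best_combo
        if len(chosen) == n:
            total = cur.sum()
            if total > best_total:
                best_total, best_combo = total, tuple(chosen)
            return
        remaining = n - len(chosen)
        if n_cfg - start < remaining:
            return
        ub = np.maximum(cur, suffix_max[start]).sum()
        if ub <= best_total:
            return
        for j in range(start, n_cfg - remaining + 1):
            search(j + 1, chosen + [j], np.maximum(cur, cc[:, j]))

    search(0, [], np.full(cc.shape[0], -np.inf))

    combo_arr = np.array(best_combo)
    per_crm: dict[str, int] = {}
    for ci, crm in enumerate(ccm.crms):
        sub = cc[ci, combo_arr]
        per_crm[crm] = int(combo_arr[int(np.argmax(sub))])
    calls: list[RoleCall] = []
    for crm in ccm.crms:
        k = per_crm[crm]
        for t, tf in enumerate(tf_names):
            role = ROLE_ACT if (k >> t) & 1 else ROLE_REP
            calls.append(RoleCall(crm, tf, role, strong=True))
    return MethodResult(f"best_{n}", best_combo, per_crm, calls)


# ---------------------------------------------------------------------------
# SENSITIVITY


def sensitivity(
    ccm: CCMatrix,
    tf_names: Sequence[str] | None = None,
    na_threshold: float = DEFAULT_EPSILON,
    strong_threshold: float = DEFAULT_STRONG_THRESHOLD,
) -> MethodResult:
    """Assign each TF, per CRM, the role whose adoption most improves the fit.

    For every configuration pair differing only in the TF's role the signed CC
    difference (activator minus repressor) is computed; the pair with the
    largest magnitude decides. Differences at or below ``na_threshold`` give
    NA; strong calls need a difference above ``strong_threshold``.
    """
    tf_names = _default_names(ccm, tf_names)
    calls: list[RoleCall] = []
    for t, tf in enumerate(tf_names):
        act_idx, rep_idx = _role_pair_indices(ccm.n_tfs, t)
        diffs = ccm.cc[:, act_idx] - ccm.cc[:, rep_idx]  # crms x pairs
        j_star = np.argmax(np.abs(diffs), axis=1)
        for ci, crm in enumerate(ccm.crms):
            dcc = float(diffs[ci, j_star[ci]])
            if abs(dcc) <= na_threshold:
                calls.append(RoleCall(crm, tf, ROLE_NA, strong=False, delta_cc=dcc))
            else:
                role = ROLE_ACT if dcc > 0 else ROLE_REP
                calls.append(
                    RoleCall(crm, tf, role, strong=abs(dcc) > strong_threshold, delta_cc=dcc)
                )
    calls.sort(key=lambda c: (list(ccm.crms).index(c.crm), tf_names.index(c.tf)))
    return MethodResult("sensitivity", (), {}, calls)


def _default_names(ccm: CCMatrix, tf_names: Sequence[str] | None) -> list[str]:
    if tf_names is None:
        return [f"TF{i}" for i in range(ccm.n_tfs)]
    if len(tf_names) != ccm.n_tfs:
        raise ValueError("tf_names length must match the matrix panel size")
    return list(tf_names)


# ---------------------------------------------------------------------------
# Summaries, ensemble, enrichment


def summarize_tf_roles(
    result: MethodResult,
    tf_names: Sequence[str],
    theta: float = DEFAULT_THETA,
) -> dict[str, MethodSummary]:
    """Per-TF single-method label: "+" or "-" when one role wins more than a
    ``theta`` share of the non-NA calls, otherwise "s" (switching)."""
    if not 0.5 < theta <= 1.0:
        raise ValueError("theta must lie in (0.5, 1]")
    out: dict[str, MethodSummary] = {}
    for tf in tf_names:
        calls = result.calls_for(tf)
        n_act = sum(1 for c in calls if c.role == ROLE_ACT)
        n_rep = sum(1 for c in calls if c.role == ROLE_REP)
        n_strong_act = sum(1 for c in calls if c.role == ROLE_ACT and c.strong)
        n_strong_rep = sum(1 for c in calls if c.role == ROLE_REP and c.strong)
        total = n_act + n_rep
        if total == 0:
            label = "s"
        elif n_act / total > theta:
            label = "+"
        elif n_rep / total > theta:
            label = "-"
        else:
            label = "s"
        out[tf] = MethodSummary(tf, label, n_act, n_rep, n_strong_act, n_strong_rep)
    return out


def ensemble_vote(summaries: Sequence[dict[str, MethodSummary]]) -> RoleSummary:
    """Majority vote of exactly three per-method summaries.

    Two or more agreeing labels win; a three-way split yields "s". Confidence
    counts the strong calls supporting the final label across all methods
    (both roles count for "s").
    """
    if len(summaries) != 3:
        raise ValueError("ensemble_vote expects exactly three method summaries")
    tfs = list(summaries[0])
    for s in summaries[1:]:
        if list(s) != tfs:
            raise ValueError("method summaries cover different TF panels")
    roles: dict[str, str] = {}
    confidence: dict[str, int] = {}
    for tf in tfs:
        labels = [s[tf].label for s in summaries]
        final = "s"
        for cand in ("+", "-", "s"):
            if labels.count(cand) >= 2:
                final = cand
                break
        roles[tf] = final
        if final == "+":
            conf = sum(s[tf].n_strong_act for s in summaries)
        elif final == "-":
            conf = sum(s[tf].n_strong_rep for s in summaries)
        else:
            conf = sum(s[tf].n_strong_act + s[tf].n_strong_rep for s in summaries)
        confidence[tf] = conf
    return RoleSummary(roles, confidence)


def _status(p: float | None, alpha: float, beta: float) -> str:
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return "untested"
    if p < alpha:
        return "over"
    if p > beta:
        return "under"
    return "background"


def enrichment_call(
    tf: str,
    p_act: float | None,
    p_rep: float | None,
    alpha: float = 0.01,
    beta: float = 0.99,
    delta: float = 0.2,
) -> EnrichmentCall:
    """Classify one activator-set/repressor-set p-value pair.

    A set is over-represented below ``alpha`` and under-represented above
    ``beta``. The pair is differentially enriched iff exactly one set is
    over-represented, the other is under-represented or background, and the
    p-values differ by more than ``delta``.
    """
    sa = _status(p_act, alpha, beta)
    sr = _status(p_rep, alpha, beta)
    differential = False
    if "untested" not in (sa, sr):
        one_over = (sa == "over") != (sr == "over")
        if one_over and abs(p_act - p_rep) > delta:
            differential = True
    if differential:
        return EnrichmentCall(tf, p_act, p_rep, sa, sr, True)
    return EnrichmentCall(tf, p_act, p_rep, sa, sr, False)


def classify_enrichment_table(table, alpha: float = 0.01, beta: float = 0.99,
                              delta: float = 0.2) -> list[EnrichmentCall]:
    """Apply :func:`enrichment_call` to a long-format p-value DataFrame."""
    calls = []
    for row in table.itertuples(index=False):
        pa = None if np.isnan(row.p_act) else float(row.p_act)
        pr = None if np.isnan(row.p_rep) else float(row.p_rep)
        calls.append(enrichment_call(f"{row.id}:{row.comparison}", pa, pr, alpha, beta, delta))
    return calls


def bundled_pvalue_table():
    """The packaged TF enrichment p-value table (long format DataFrame)."""
    from importlib.resources import files

    from .io_formats import read_pvalue_table

    return read_pvalue_table(files("dualtf").joinpath("data/tf_enrichment_pvalues.tsv"))


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-corrected p-value ``min(1, p * n_tests)``."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return min(1.0, p * n_tests)
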