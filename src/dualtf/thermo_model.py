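"""Thermodynamic CRM expression model with short-range quenching.

Each predicted site is occupied according to a single-site binding isotherm
``f = K v q / (1 + K v q)`` where ``v`` is the TF concentration at an axis
position and ``q`` the site's normalized affinity. Activator sites contribute
``E_act * f``, attenuated multiplicatively by ``(1 - E_rep * f_rep)`` for each
occupied repressor site whose center lies within ``d`` base pairs. The summed
activation drives a logistic transcription gate with threshold ``G0`` and
ceiling ``R0``.

Which TFs act as activators versus repressors is given by a
:class:`Configuration`; a TF declared *dual* may take a different role on
different CRMs, with separate activator and repressor effectiveness
parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import ProfileSet
from .site_scanner import TFBS

logger = logging.getLogger(__name__)

#: Default quench distance (bp) between site centers.
DEFAULT_QUENCH_DISTANCE = 100.0

ACT, REP = 1, -1


@dataclass(frozen=True)
class Configuration:
    """An activator(+1)/repressor(-1) role assignment over an ordered TF panel.

    The integer encoding sets bit ``i`` iff TF ``i`` is an activator, so a
    panel of ``n`` TFs has configurations ``0 .. 2**n - 1``.
    """

    roles: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.roles or any(r not in (ACT, REP) for r in self.roles):
            raise ValueError("roles must be a non-empty vector over {+1, -1}")

    @property
    def n(self) -> int:
        return len(self.roles)

    @property
    def index(self) -> int:
        return sum(1 << i for i, r in enumerate(self.roles) if r == ACT)

    @classmethod
    def from_index(cls, index: int, n: int) -> "Configuration":
        if not 0 <= index < (1 << n):
            raise ValueError(f"index {index} out of range for {n} TFs")
        return cls(tuple(ACT if (index >> i) & 1 else REP for i in range(n)))

    def with_role(self, i: int, role: int) -> "Configuration":
        roles = list(self.roles)
        roles[i] = role
        return Configuration(tuple(roles))

    def role_of(self, i: int) -> int:
        return self.roles[i]


@dataclass(frozen=True)
class TFPanel:
    """Ordered TF names plus their published role assignment."""

    names: tuple[str, ...]
    literature_roles: Configuration

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("TF names must be unique")
        if len(self.names) != self.literature_roles.n:
            raise ValueError("literature_roles length must match the panel size")

    @property
    def n(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"TF {name!r} not in panel") from None


#: The eight gap-gene TFs with their published roles
#: (Bcd, Cad, TorRE activators; Hb, Tll, Gt, Kr, Kni repressors).
GAP_GENE_PANEL = TFPanel(
    names=("Bcd", "Cad", "Hb", "Tll", "Gt", "Kr", "Kni", "TorRE"),
    literature_roles=Configuration((ACT, ACT, REP, REP, REP, REP, REP, ACT)),
)


@dataclass(frozen=True)
class ModelParams:
    """Thermodynamic parameter vector for a TF panel.

    ``K`` and the effectiveness arrays are indexed by panel position. For a
    non-dual TF only the effectiveness matching its configured role is
    meaningful (the other entry is inert); dual TFs use ``E_act`` on CRMs
    where they activate and ``E_rep`` where they repress.
    """

    names: tuple[str, ...]
    K: np.ndarray
    E_act: np.ndarray
    E_rep: np.ndarray
    G0: float
    R0: float
    d: float = DEFAULT_QUENCH_DISTANCE
    dual_tfs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        n = len(self.names)
        K = np.asarray(self.K, dtype=float)
        E_act = np.asarray(self.E_act, dtype=float)
        E_rep = np.asarray(self.E_rep, dtype=float)
        for label, arr in (("K", K), ("E_act", E_act), ("E_rep", E_rep)):
            if arr.shape != (n,):
                raise ValueError(f"{label} must have one entry per TF")
        if np.any(K <= 0):
            raise ValueError("association constants K must be positive")
        if np.any(E_act < 0):
            raise ValueError("activator effectiveness must be non-negative")
        if np.any((E_rep < 0) | (E_rep > 1)):
            raise ValueError("repressor effectiveness must lie in [0, 1]")
        if self.R0 <= 0:
            raise ValueError("maximal rate R0 must be positive")
        if self.d < 0:
            raise ValueError("quench distance d must be non-negative")
        unknown = set(self.dual_tfs) - set(self.names)
        if unknown:
            raise ValueError(f"dual TFs not in panel: {sorted(unknown)}")
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "E_act", E_act)
        object.__setattr__(self, "E_rep", E_rep)
        object.__setattr__(self, "dual_tfs", frozenset(self.dual_tfs))

    def index_of(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class ExpressionProfile:
    """Observed or predicted transcription rate along the axis."""

    axis: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis.shape != self.values.shape:
            raise ValueError("axis and values must have the same length")


def site_occupancy(q, v, K):
    """Fractional occupancy ``K v q / (1 + K v q)`` of a site.

    Accepts scalars or arrays; monotone increasing in each argument and
    strictly below 1.
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(q <= 0) or np.any(q > 1):
        raise ValueError("normalized affinity q must lie in (0, 1]")
    if np.any(v < 0):
        raise ValueError("concentration must be non-negative")
    if np.any(np.asarray(K, dtype=float) <= 0):
        raise ValueError("association constant K must be positive")
    x = K * v * q
    return x / (1.0 + x)


def total_activation(
    sites: Sequence[TFBS],
    conc_at_x: Mapping[str, float],
    params: ModelParams,
    roles_for_crm: Configuration,
) -> float:
    """Summed, quenched activator contribution at one axis position.

    Reference per-position implementation; :func:`predict_expression` must
    agree with it at every position.
    """
    idx = {name: i for i, name in enumerate(params.names)}
    for s in sites:
        if s.tf not in idx:
            raise KeyError(f"site TF {s.tf!r} not in parameter panel")
    activators = [s for s in sites if roles_for_crm.role_of(idx[s.tf]) == ACT]
    repressors = [s for s in sites if roles_for_crm.role_of(idx[s.tf]) == REP]
    total = 0.0
    for a in activators:
        ia = idx[a.tf]
        fa = site_occupancy(a.q, conc_at_x[a.tf], params.K[ia])
        term = params.E_act[ia] * fa
        for r in repressors:
            if abs(a.center - r.center) <= params.d:
                ir = idx[r.tf]
                fr = site_occupancy(r.q, conc_at_x[r.tf], params.K[ir])
                term *= 1.0 - params.E_rep[ir] * fr
        total += term
    return float(total)


def transcription_rate(sigma, G0: float, R0: float):
    """Logistic gate ``R0 / (1 + exp(-(sigma - G0)))``."""
    return R0 / (1.0 + np.exp(-(np.asarray(sigma, dtype=float) - G0)))


def predict_expression(
    crm_sites: Sequence[TFBS],
    concentrations: ProfileSet,
    params: ModelParams,
    roles_for_crm: Configuration,
) -> ExpressionProfile:
    """Predict the expression profile of one CRM over the concentration axis."""
    idx = {name: i for i, name in enumerate(params.names)}
    for s in crm_sites:
        if s.tf not in idx:
            raise KeyError(f"site TF {s.tf!r} not in parameter panel")
        if s.tf not in concentrations:
            raise KeyError(f"no concentration track for TF {s.tf!r}")
    n_pos = concentrations.axis.size
    if not crm_sites:
        sigma = np.zeros(n_pos)
        return ExpressionProfile(concentrations.axis, transcription_rate(sigma, params.G0, params.R0))

    tf_i = np.array([idx[s.tf] for s in crm_sites])
    q = np.array([s.q for s in crm_sites])
    centers = np.array([s.center for s in crm_sites])
    roles = np.array([roles_for_crm.role_of(i) for i in tf_i])
    V = np.stack([concentrations[s.tf] for s in crm_sites])  # sites x positions

    x = params.K[tf_i, None] * V * q[:, None]
    f = x / (1.0 + x)

    is_act = roles == ACT
    is_rep = roles == REP
    A = params.E_act[tf_i[is_act], None] * f[is_act]  # act sites x positions
    if is_rep.any() and is_act.any():
        fr = f[is_rep]
        quench_one = 1.0 - params.E_rep[tf_i[is_rep], None] * fr  # in (0, 1]
        within = (
            np.abs(centers[is_act][:, None] - centers[is_rep][None, :]) <= params.d
        )  # act x rep
        # product over in-range repressors via a log-space matrix product
        A = A * np.exp(within @ np.log(quench_one))
    sigma = A.sum(axis=0) if A.size else np.zeros(n_pos)
    return ExpressionProfile(concentrations.axis, transcription_rate(sigma, params.G0, params.R0))


def pearson_cc(observed: ExpressionProfile, predicted: ExpressionProfile) -> float:
    """Pearson correlation of two profiles on the same axis.

    A profile with zero variance yields 0 by convention (a constant carries
    no shape information); the event is logged.
    """
    if observed.axis.shape != predicted.axis.shape or not np.allclose(
        observed.axis, predicted.axis
    ):
        raise ValueError("profiles are on different axes")
    a, b = observed.values, predicted.values
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        logger.warning("zero-variance profile in correlation; returning 0")
        return 0.0
    return float(np.clip(np.corrcoef(a, b)[0, 1], -1.0, 1.0))


def count_free_parameters(
    model: str,
    n: int,
    dual_tfs: Iterable[str] = (),
    pwm_total_width: int | None = None,
    n_crms: int | None = None,
) -> int:
    """Free-parameter count of a model variant.

    ``reinitz``: per-TF association and effectiveness constants plus the two
    global gate parameters, ``2n + 2``, plus one extra effectiveness per
    dual-function TF. ``segal``: ``3n + 3|W| + |C|`` where ``|W|`` is the
    summed PWM width and ``|C|`` the number of CRMs.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    dual = list(dual_tfs)
    if model == "reinitz":
        return 2 * n + 2 + len(dual)
    if model == "segal":
        if pwm_total_width is None or n_crms is None:
            raise ValueError("segal count requires pwm_total_width and n_crms")
        return 3 * n + 3 * pwm_total_width + n_crms
    raise ValueError(f"unknown model {model!r}")
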