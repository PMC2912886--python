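"""Synthetic datasets with the structure the role-inference pipeline assumes.

A generated dataset mirrors the gap-gene design at desk scale: per-TF
concentration gradients over an axis, CRM sequences with planted consensus
binding sites, expression profiles produced by the forward thermodynamic
model (plus optional Gaussian noise), and optionally one TF planted with
*dual* function — activator on one subset of CRMs, repressor on the rest.
Protein sequences with controlled SUMO-consensus content round out the
end-to-end experiment.

Everything is byte-reproducible from ``spec.seed``; each stage derives its
own independent stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_formats import PROTEIN_CHARS, ProfileSet, SequenceSet
from .sa_optimizer import Dataset
from .site_scanner import (
    DEFAULT_THRESHOLD_BITS,
    DNA_ALPHABET,
    PWM,
    TFBS,
    TFBSMap,
    UNIFORM_BACKGROUND,
    reverse_complement,
    scan_crm,
)
from .sumo_scanner import ConsensusPattern, PSI_KXE, scan_consensus
from .thermo_model import (
    ACT,
    REP,
    Configuration,
    ModelParams,
    TFPanel,
    predict_expression,
)

_SALTS = {"conc": 11, "seq": 23, "expr": 37, "protein": 53}

GRADIENT_SHAPES = ("anterior_exp", "posterior_exp", "gaussian_bump")


@dataclass(frozen=True)
class TFSpec:
    """Gradient shape and binding preference of one synthetic TF."""

    name: str
    gradient: str  # anterior_exp | posterior_exp | gaussian_bump
    loc: float  # decay length for exponentials, bump center for gaussians
    width: float = 15.0  # bump SD; unused for exponentials
    consensus: str = ""
    base_prob: float = 0.95  # PWM mass on the consensus base per column

    def __post_init__(self) -> None:
        if self.gradient not in GRADIENT_SHAPES:
            raise ValueError(f"unknown gradient shape {self.gradient!r}")
        if not 0.25 < self.base_prob < 1.0 + 1e-12:
            raise ValueError("base_prob must exceed the background rate 0.25")

    def pwm(self, background: np.ndarray) -> PWM:
        probs = np.full((len(self.consensus), 4), (1.0 - self.base_prob) / 3.0)
        for i, base in enumerate(self.consensus):
            probs[i, DNA_ALPHABET.index(base)] = self.base_prob
        return PWM(self.name, probs, background)


@dataclass
class GeneratorSpec:
    """Full recipe for one synthetic dataset."""

    tf_specs: list[TFSpec]
    base_roles: Configuration  # roles of every TF outside the dual split
    n_crms: int = 8
    crm_length: int = 500
    n_positions: int = 50
    sites_per_tf: int = 2  # planted sites per TF per CRM
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    noise_sd: float = 0.0
    dual_tf: str | None = None
    dual_act_crms: tuple[int, ...] = ()  # CRM indices where the dual TF activates
    params: ModelParams | None = None
    scan_threshold: float = DEFAULT_THRESHOLD_BITS
    min_gap: int = 5
    ensure_exact_scan: bool = True
    pair_repressors: bool = True  # drop repressor sites near activator sites
    seed: int = 0

    def __post_init__(self) -> None:
        names = [t.name for t in self.tf_specs]
        if len(set(names)) != len(names):
            raise ValueError("TF names must be unique")
        if self.base_roles.n != len(names):
            raise ValueError("base_roles size must match tf_specs")
        bg = np.asarray(self.background, dtype=float)
        if abs(bg.sum() - 1.0) > 1e-6:
            raise ValueError("background frequencies must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dual_tf is not None and self.dual_tf not in names:
            raise ValueError(f"dual TF {self.dual_tf!r} not among TF specs")
        if any(not 0 <= i < self.n_crms for i in self.dual_act_crms):
            raise ValueError("dual_act_crms index out of range")
        self.background = bg
        if self.params is None:
            self.params = default_truth_params(tuple(names))
        for spec in self.tf_specs:
            if not spec.consensus:
                raise ValueError(f"TF {spec.name!r} has no consensus sequence")
            pwm = spec.pwm(bg)
            if pwm.s_max < self.scan_threshold:
                raise ValueError(
                    f"TF {spec.name!r}: s_max {pwm.s_max:.2f} bits below the scan "
                    f"threshold {self.scan_threshold}; lengthen the consensus"
                )

    @property
    def tf_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.tf_specs)

    @property
    def panel(self) -> TFPanel:
        return TFPanel(self.tf_names, self.base_roles)

    def pwms(self) -> list[PWM]:
        return [t.pwm(self.background) for t in self.tf_specs]

    def crm_ids(self) -> list[str]:
        return [f"crm{i:02d}" for i in range(self.n_crms)]

    def config_for_crm(self, crm_index: int) -> Configuration:
        """Ground-truth configuration; differs from base only in the dual TF."""
        cfg = self.base_roles
        if self.dual_tf is not None:
            t = self.tf_names.index(self.dual_tf)
            role = ACT if crm_index in self.dual_act_crms else REP
            cfg = cfg.with_role(t, role)
        return cfg


@dataclass
class SyntheticDataset:
    """A generated dataset plus its generating truth."""

    spec: GeneratorSpec
    crms: SequenceSet
    pwms: list[PWM]
    concentrations: ProfileSet
    observed: ProfileSet
    truth_sites: TFBSMap
    per_crm_configs: dict[str, Configuration]

    @property
    def params(self) -> ModelParams:
        return self.spec.params

    @property
    def panel(self) -> TFPanel:
        return self.spec.panel

    def to_dataset(self, sites: TFBSMap | None = None) -> Dataset:
        """Package into a fit-ready :class:`Dataset` (truth sites by default)."""
        site_map = sites if sites is not None else self.truth_sites
        return Dataset(
            tf_names=self.spec.tf_names,
            crm_ids=tuple(self.spec.crm_ids()),
            sites={c: list(site_map[c]) for c in self.spec.crm_ids()},
            concentrations=self.concentrations,
            observed=self.observed,
        )


def default_truth_params(names: tuple[str, ...], dual_tfs: frozenset[str] = frozenset(),
                         d: float = 100.0) -> ModelParams:
    # tuned so profiles span the gate's dynamic range instead of saturating
    n = len(names)
    return ModelParams(
        names=names,
        K=np.full(n, 3.0),
        E_act=np.full(n, 2.0),
        E_rep=np.full(n, 0.95),
        G0=2.0,
        R0=1.0,
        d=d,
        dual_tfs=dual_tfs,
    )


def _rng(spec: GeneratorSpec, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([_SALTS[stage], int(spec.seed)]))


def _random_consensi(n: int, length: int, rng: np.random.Generator,
                     min_hamming: int = 3) -> list[str]:
    """Random consensus sequences pairwise (and reverse-complement) distant."""

    def hamming(a: str, b: str) -> int:
        return sum(x != y for x, y in zip(a, b))

    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not draw sufficiently distinct consensi")
        cand = "".join(rng.choice(list(DNA_ALPHABET), size=length))
        pool = chosen + [cand]
        ok = True
        for s in pool:
            for u in pool:
                if s is not u and min(hamming(s, u), hamming(s, reverse_complement(u))) < min_hamming:
                    ok = False
            if hamming(cand, reverse_complement(cand)) < min_hamming:
                ok = False
        if ok:
            chosen.append(cand)
    return chosen


def default_spec(
    n_tfs: int = 4,
    n_crms: int = 8,
    crm_length: int = 500,
    n_positions: int = 50,
    noise_sd: float = 0.0,
    dual_tf: str | None = "TF1",
    seed: int = 0,
    consensus_length: int = 8,
    **overrides,
) -> GeneratorSpec:
    """Desk-scale default: alternating gradients, one planted dual TF.

    TFs are named ``TF0 .. TF{n-1}``. Even-indexed TFs are activators and
    odd-indexed TFs repressors in the base configuration; the dual TF (by
    default ``TF1``) activates on the first half of the CRMs and represses on
    the rest.
    """
    if n_tfs < 2:
        raise ValueError("need at least 2 TFs")
    rng = np.random.default_rng(np.random.SeedSequence([97, int(seed)]))
    consensi = _random_consensi(n_tfs, consensus_length, rng)
    # broad exponentials so activator occupancy persists across the bumps'
    # domains; otherwise mid-axis repressors have nothing to quench
    shapes = [
        ("anterior_exp", 30.0),
        ("gaussian_bump", 40.0),
        ("posterior_exp", 30.0),
        ("gaussian_bump", 70.0),
    ]
    tf_specs = []
    for i in range(n_tfs):
        shape, loc = shapes[i % len(shapes)]
        # stagger bump centers when the panel is large
        if shape == "gaussian_bump" and i >= len(shapes):
            loc = 20.0 + 15.0 * (i % 5)
        tf_specs.append(TFSpec(f"TF{i}", shape, loc, consensus=consensi[i]))
    roles = Configuration(tuple(ACT if i % 2 == 0 else REP for i in range(n_tfs)))
    return GeneratorSpec(
        tf_specs=tf_specs,
        base_roles=roles,
        n_crms=n_crms,
        crm_length=crm_length,
        n_positions=n_positions,
        noise_sd=noise_sd,
        dual_tf=dual_tf,
        dual_act_crms=tuple(range(n_crms // 2)) if dual_tf else (),
        seed=seed,
        **overrides,
    )


def make_concentration_profiles(spec: GeneratorSpec) -> ProfileSet:
    """Per-TF gradient tracks over the axis, each scaled to a maximum of 1."""
    x = np.linspace(0.0, 100.0, spec.n_positions)
    profiles: dict[str, np.ndarray] = {}
    for tf in spec.tf_specs:
        if tf.gradient == "anterior_exp":
            v = np.exp(-x / tf.loc)
        elif tf.gradient == "posterior_exp":
            v = np.exp(-(100.0 - x) / tf.loc)
        else:
            v = np.exp(-((x - tf.loc) ** 2) / (2.0 * tf.width**2))
        profiles[tf.name] = v / v.max()
    return ProfileSet(x, profiles, non_negative=True)


def _plant_positions(n_sites: int, lengths: list[int], crm_length: int, min_gap: int,
                     rng: np.random.Generator, max_tries: int = 2000) -> list[int]:
    taken: list[tuple[int, int]] = []
    starts: list[int] = []
    for L in lengths:
        starts.append(_place_one(L, crm_length, min_gap, taken, rng, max_tries))
    return starts


def _place_one(L: int, crm_length: int, min_gap: int, taken: list[tuple[int, int]],
               rng: np.random.Generator, max_tries: int = 2000,
               window: tuple[int, int] | None = None) -> int:
    lo, hi = window if window else (0, crm_length - L)
    lo, hi = max(lo, 0), min(hi, crm_length - L)
    if hi < lo:
        lo, hi = 0, crm_length - L
    for attempt in range(max_tries):
        s = int(rng.integers(lo, hi + 1))
        if all(s + L + min_gap <= a or b + min_gap <= s for a, b in taken):
            taken.append((s, s + L))
            return s
        if window and attempt == max_tries // 2:
            lo, hi = 0, crm_length - L  # anchor region crowded; fall back
    raise ValueError(
        f"cannot place a {L} bp site in a {crm_length} bp CRM with gap {min_gap}"
    )


def make_crm_sequences(spec: GeneratorSpec) -> tuple[SequenceSet, TFBSMap]:
    """Background-sampled CRMs with planted consensus sites.

    Planted sites are non-overlapping and separated by at least ``min_gap``
    bp, on a uniformly chosen strand. Activator-role sites (per the CRM's
    ground-truth configuration) are placed uniformly at random; with
    ``pair_repressors`` set, each repressor-role site is dropped near a
    randomly chosen activator site so that quenching interactions are always
    exercised. When ``ensure_exact_scan`` is set, each CRM is resampled until
    rescanning recovers exactly the planted sites and nothing else.
    """
    rng = _rng(spec, "seq")
    pwms = spec.pwms()
    records: list[tuple[str, str]] = []
    truth: dict[str, list[TFBS]] = {}
    bases = np.array(list(DNA_ALPHABET))
    reach = int(max(spec.params.d * 0.6, 20))
    for ci, crm_id in enumerate(spec.crm_ids()):
        cfg = spec.config_for_crm(ci)
        role_of = {p.name: cfg.role_of(i) for i, p in enumerate(pwms)}
        for _ in range(200):
            act_jobs = [p for p in pwms if role_of[p.name] == ACT
                        for _ in range(spec.sites_per_tf)]
            rep_jobs = [p for p in pwms if role_of[p.name] == REP
                        for _ in range(spec.sites_per_tf)]
            taken: list[tuple[int, int]] = []
            placed: list[tuple[PWM, int]] = []
            act_starts: list[int] = []
            for pwm in act_jobs:
                s = _place_one(pwm.length, spec.crm_length, spec.min_gap, taken, rng)
                placed.append((pwm, s))
                act_starts.append(s)
            for pwm in rep_jobs:
                window = None
                if spec.pair_repressors and act_starts:
                    anchor = act_starts[int(rng.integers(len(act_starts)))]
                    window = (anchor - reach, anchor + reach)
                s = _place_one(pwm.length, spec.crm_length, spec.min_gap, taken, rng,
                               window=window)
                placed.append((pwm, s))
            seq = rng.choice(bases, size=spec.crm_length, p=spec.background)
            sites: list[TFBS] = []
            for pwm, start in placed:
                strand = "+" if rng.random() < 0.5 else "-"
                planted = pwm.consensus if strand == "+" else reverse_complement(pwm.consensus)
                seq[start : start + pwm.length] = list(planted)
                sites.append(
                    TFBS(start=start, tf=pwm.name, strand=strand,
                         score=pwm.s_max, q=1.0, length=pwm.length)
                )
            seq_str = "".join(seq)
            if not spec.ensure_exact_scan:
                break
            rescanned = sorted(
                s for pwm in pwms for s in scan_crm(pwm, seq_str, spec.scan_threshold)
            )
            if rescanned == sorted(sites):
                break
        else:
            raise RuntimeError(f"CRM {crm_id}: could not realize an exact-scan sequence")
        records.append((crm_id, seq_str))
        truth[crm_id] = sorted(sites)
    return SequenceSet(records, alphabet="dna"), TFBSMap(truth)


def make_expression(
    truth_sites: TFBSMap,
    concentrations: ProfileSet,
    spec: GeneratorSpec,
) -> ProfileSet:
    """Forward-model expression per CRM plus Gaussian noise, clipped at 0."""
    rng = _rng(spec, "expr")
    profiles: dict[str, np.ndarray] = {}
    for ci, crm_id in enumerate(spec.crm_ids()):
        pred = predict_expression(
            truth_sites[crm_id], concentrations, spec.params, spec.config_for_crm(ci)
        )
        values = pred.values
        if spec.noise_sd > 0:
            values = np.clip(values + rng.normal(0.0, spec.noise_sd, values.shape), 0.0, None)
        profiles[crm_id] = values
    return ProfileSet(concentrations.axis, profiles, non_negative=True)


def generate(spec: GeneratorSpec) -> SyntheticDataset:
    """Run every generation stage and bundle the outputs with their truth."""
    conc = make_concentration_profiles(spec)
    crms, truth_sites = make_crm_sequences(spec)
    observed = make_expression(truth_sites, conc, spec)
    configs = {
        crm_id: spec.config_for_crm(ci) for ci, crm_id in enumerate(spec.crm_ids())
    }
    return SyntheticDataset(
        spec=spec,
        crms=crms,
        pwms=spec.pwms(),
        concentrations=conc,
        observed=observed,
        truth_sites=truth_sites,
        per_crm_configs=configs,
    )


_AA = sorted(PROTEIN_CHARS)


def make_protein_set(
    tf_labels: Mapping[str, str],
    seed: int = 0,
    length: int = 200,
    pattern: ConsensusPattern = PSI_KXE,
    planted_counts: Mapping[str, int] | None = None,
) -> SequenceSet:
    """Random protein sequences whose SUMO-consensus content follows the labels.

    TFs labelled ``"s"`` (switching) receive planted pattern instances (one by
    default) and are rejection-sampled until the scan count equals the planted
    number exactly; single-role TFs are rejection-sampled to zero matches.
    """
    rng = np.random.default_rng(np.random.SeedSequence([_SALTS["protein"], int(seed)]))
    w = len(pattern.positions)
    records: list[tuple[str, str]] = []
    for tf, label in tf_labels.items():
        want = (planted_counts or {}).get(tf, 1) if label == "s" else 0
        for _ in range(500):
            seq = list(rng.choice(_AA, size=length))
            if want:
                starts = _plant_positions(want, [w] * want, length, 2, rng)
                for s in starts:
                    instance = [str(rng.choice(sorted(allowed))) for allowed in pattern.positions]
                    seq[s : s + w] = instance
            seq_str = "".join(seq)
            if len(scan_consensus(seq_str, pattern)) == want:
                break
        else:
            raise RuntimeError(f"could not realize a protein for {tf!r} with {want} matches")
        records.append((tf, seq_str))
    return SequenceSet(records, alphabet="protein")
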