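"""Dual-function retraining experiment.

Per-CRM roles for a chosen subset of TFs are taken from the SENSITIVITY
method (falling back to the published role where SENSITIVITY made no call);
all other TFs keep their published role. Each variant — the single-role
baseline plus each dual subset — is then retrained simultaneously on all
CRMs under an identical annealing budget and master seed, with the dual TFs
given split activator/repressor effectiveness, and the variants are compared
on parameter count and mean fit correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .role_analysis import MethodResult, ROLE_ACT, ROLE_NA, ROLE_REP
from .sa_optimizer import Dataset, SASchedule, sa_fit
from .thermo_model import (
    ACT,
    REP,
    Configuration,
    DEFAULT_QUENCH_DISTANCE,
    TFPanel,
    count_free_parameters,
)


@dataclass
class DualAssignment:
    """Per-CRM role of each dual TF plus the resulting configurations."""

    dual_tfs: tuple[str, ...]
    per_crm_roles: dict[str, dict[str, str]]  # crm -> tf -> ACT | REP
    per_crm_config: dict[str, Configuration]

    @property
    def n_distinct_configs(self) -> int:
        return len({cfg.index for cfg in self.per_crm_config.values()})


@dataclass
class VariantRow:
    variant: str
    n_configs: int
    n_params: int
    mean_cc: float
    se_cc: float
    per_crm_cc: dict[str, float]


@dataclass
class VariantReport:
    rows: list[VariantRow]

    def row(self, variant: str) -> VariantRow:
        for r in self.rows:
            if r.variant == variant:
                return r
        raise KeyError(variant)


def variant_name(dual_tfs: Sequence[str]) -> str:
    return "baseline" if not dual_tfs else "".join(dual_tfs) + "Dual"


def assign_dual_roles(
    sens: MethodResult,
    dual_tfs: Sequence[str],
    panel: TFPanel,
    crm_ids: Sequence[str],
) -> DualAssignment:
    """Turn SENSITIVITY calls into per-CRM configurations for the dual TFs.

    CRMs where SENSITIVITY called NA keep the TF's published role; non-dual
    TFs are fixed at their published roles throughout.
    """
    for tf in dual_tfs:
        panel.index_of(tf)  # raises KeyError for unknown TFs
    calls = {(c.crm, c.tf): c for c in sens.calls}
    per_crm_roles: dict[str, dict[str, str]] = {}
    per_crm_config: dict[str, Configuration] = {}
    for crm in crm_ids:
        cfg = panel.literature_roles
        roles: dict[str, str] = {}
        for tf in dual_tfs:
            t = panel.index_of(tf)
            call = calls.get((crm, tf))
            if call is None or call.role == ROLE_NA:
                role = cfg.role_of(t)
            else:
                role = ACT if call.role == ROLE_ACT else REP
            roles[tf] = ROLE_ACT if role == ACT else ROLE_REP
            cfg = cfg.with_role(t, role)
        per_crm_roles[crm] = roles
        per_crm_config[crm] = cfg
    return DualAssignment(tuple(dual_tfs), per_crm_roles, per_crm_config)


def run_dual_experiment(
    dataset: Dataset,
    panel: TFPanel,
    dual_variants: Sequence[Sequence[str]],
    schedule: SASchedule,
    sens: MethodResult,
    bounds: Mapping[str, tuple] | None = None,
    d: float = DEFAULT_QUENCH_DISTANCE,
) -> VariantReport:
    """Train the baseline and every dual variant simultaneously on all CRMs.

    All variants share the annealing schedule and master seed so that
    differences in mean CC reflect model structure, not search luck.
    """
    rows: list[VariantRow] = []
    for dual in [()] + [tuple(v) for v in dual_variants]:
        if dual:
            assignment = assign_dual_roles(sens, dual, panel, dataset.crm_ids)
            roles_per_crm = assignment.per_crm_config
            n_configs = assignment.n_distinct_configs
        else:
            roles_per_crm = {crm: panel.literature_roles for crm in dataset.crm_ids}
            n_configs = 1
        fit = sa_fit(
            dataset,
            roles_per_crm,
            schedule,
            bounds=bounds,
            dual_tfs=frozenset(dual),
            d=d,
        )
        rows.append(
            VariantRow(
                variant=variant_name(dual),
                n_configs=n_configs,
                n_params=count_free_parameters("reinitz", panel.n, dual),
                mean_cc=fit.mean_cc,
                se_cc=fit.se_cc,
                per_crm_cc=fit.per_crm_cc,
            )
        )
    return VariantReport(rows)


def write_variant_report(report: VariantReport, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("variant\tn_configs\tn_params\tmean_cc\tse_cc\n")
        for r in report.rows:
            fh.write(f"{r.variant}\t{r.n_configs}\t{r.n_params}\t{r.mean_cc:.6f}\t{r.se_cc:.6f}\n")
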