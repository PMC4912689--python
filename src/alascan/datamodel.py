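"""Shared domain types for the alanine-scan pharmacology pipeline.

Everything downstream of the raw CSV tables speaks in terms of these
containers: typed records for the three input tables (concentration-response,
competition binding, cell-surface expression), result dataclasses for the
fitted quantities, and the validated run configuration.

Conventions used throughout the package:

* concentrations are stored in molar and fitted in log10 molar; a
  concentration of exactly 0 marks a basal (no-ligand) well and anchors the
  Bottom parameter,
* affinities and potencies are on the -log10 molar scale (pKi, pIC50, pEC50),
* operational efficacy is log10 tau; the expression-corrected variant is
  log10 tau_c,
* standard errors are SEMs over independent experiments unless stated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator


# --------------------------------------------------------------------------
# enums
# --------------------------------------------------------------------------

class ConstructKind(str, enum.Enum):
    wild_type = "wild_type"
    point_mutant = "point_mutant"


class Region(str, enum.Enum):
    ECL1 = "ECL1"
    ECL2 = "ECL2"
    ECL3 = "ECL3"
    TM_boundary = "TM_boundary"
    other = "other"


class FitStatus(str, enum.Enum):
    ok = "ok"
    no_response = "no_response"
    no_binding = "no_binding"
    not_converged = "not_converged"
    ka_fixed = "ka_fixed"
    not_determined = "not_determined"


class HeatCategory(str, enum.Enum):
    """Fold-change color classes for mutational effects.

    The integer codes are what gets written into PDB B-factor columns.
    """

    no_effect = "no_effect"
    fold_3_5 = "fold_3_5"
    fold_5_10 = "fold_5_10"
    fold_10_30 = "fold_10_30"
    fold_gt_30 = "fold_gt_30"
    enhanced = "enhanced"
    not_determined = "not_determined"

    @property
    def code(self) -> int:
        return _HEAT_CODES[self]


_HEAT_CODES = {
    HeatCategory.no_effect: 0,
    HeatCategory.fold_3_5: 1,
    HeatCategory.fold_5_10: 2,
    HeatCategory.fold_10_30: 3,
    HeatCategory.fold_gt_30: 4,
    HeatCategory.enhanced: 5,
    HeatCategory.not_determined: -1,
}

HEAT_CATEGORY_BY_CODE = {v: k for k, v in _HEAT_CODES.items()}

#: viewer legend matching the published color convention
CATEGORY_COLORS = {
    HeatCategory.no_effect: "teal",
    HeatCategory.fold_3_5: "yellow",
    HeatCategory.fold_5_10: "pale_orange",
    HeatCategory.fold_10_30: "orange",
    HeatCategory.fold_gt_30: "red",
    HeatCategory.enhanced: "blue",
    HeatCategory.not_determined: "gray",
}


class SummaryClass(str, enum.Enum):
    """Cross-ligand summary of a residue's mutational phenotype."""

    global_all_ligands = "global_all_ligands"
    selective_single_ligand = "selective_single_ligand"
    shared_two_ligands = "shared_two_ligands"
    enhanced = "enhanced"
    mixed = "mixed"
    none = "none"


# --------------------------------------------------------------------------
# constructs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Construct:
    """A receptor construct: the wild-type or a single point mutant."""

    construct_id: str
    kind: ConstructKind
    position: Optional[int] = None
    wt_residue: Optional[str] = None
    mut_residue: Optional[str] = None
    region: Region = Region.other

    def __post_init__(self) -> None:
        if self.kind is ConstructKind.point_mutant and self.position is None:
            raise ValueError(
                f"point mutant {self.construct_id!r} requires a residue position"
            )
        if self.kind is ConstructKind.wild_type and self.position is not None:
            raise ValueError("wild-type construct must not carry a position")


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Three-parameter logistic fit pooled over independent experiments."""

    pec50: float = np.nan
    top: float = np.nan
    bottom: float = np.nan
    sem_pec50: float = np.nan
    sem_top: float = np.nan
    sem_bottom: float = np.nan
    n_experiments: int = 0
    converged: bool = False
    extrapolated: bool = False
    status: FitStatus = FitStatus.ok
    #: per-experiment parameter estimates (columns: experiment_id, pec50, top, bottom)
    per_experiment: Optional[pd.DataFrame] = None

    @property
    def emax(self) -> float:
        return self.top


@dataclass
class AffinityEstimate:
    """Competition-binding affinity after Cheng-Prusoff correction."""

    pic50: float = np.nan
    pki: float = np.nan
    sem_pki: float = np.nan
    n_experiments: int = 0
    method: str = "cheng_prusoff"
    status: FitStatus = FitStatus.ok
    #: per-experiment pKi values (columns: experiment_id, pic50, pki)
    per_experiment: Optional[pd.DataFrame] = None


@dataclass
class OperationalFit:
    """Operational-model estimates for one construct x ligand x pathway."""

    construct_id: str = ""
    ligand_id: str = ""
    pathway_id: str = ""
    log_tau: float = np.nan
    log_ka: float = np.nan
    em: float = np.nan
    bottom: float = np.nan
    sem_log_tau: float = np.nan
    #: systematic part of sem_log_tau inherited from the anchored K_A
    #: (zero when K_A is freely fitted); shared across experiments, so it is
    #: excluded from per-experiment scatter but counted in difference SEMs
    sem_log_tau_sys: float = 0.0
    sem_log_ka: float = np.nan
    cov_log_tau_log_ka: float = 0.0
    n_experiments: int = 0
    status: FitStatus = FitStatus.ok
    #: per-experiment estimates (columns: experiment_id, log_tau, log_ka, em, bottom)
    per_experiment: Optional[pd.DataFrame] = None

    @property
    def derived_pec50(self) -> float:
        """pEC50 implied by the fit: with transducer slope 1 the model's
        half-maximal concentration is EC50 = K_A / (tau + 1), so
        pEC50 = -log_ka + log10(10**log_tau + 1)."""
        return -self.log_ka + np.log10(10.0 ** self.log_tau + 1.0)


@dataclass
class CorrectedEfficacy:
    """log tau after normalization to relative cell-surface expression."""

    log_tau_c: float = np.nan
    sem_log_tau_c: float = np.nan
    expression_fraction_used: float = np.nan
    status: FitStatus = FitStatus.ok
    reason: str = ""
    #: per-experiment log_tau_c values (shifted copies of the tau series)
    per_experiment: Optional[pd.DataFrame] = None


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

class RunConfig(BaseModel):
    """Validated analysis configuration.

    Defaults encode the study design this pipeline reproduces: GLP-1 as the
    reference ligand, cAMP accumulation as the reference pathway, Dunnett
    significance at alpha 0.05 and fold-change bins at 3/5/10/30.
    """

    reference_ligand_id: str = "GLP-1"
    reference_pathway_id: str = "cAMP"
    wild_type_id: str = "WT"
    tracer_kd: float = Field(default=1e-9, gt=0, description="tracer Kd, molar")
    tracer_conc: float = Field(default=5e-10, gt=0, description="tracer concentration, molar")
    em_policy: str = "shared_per_pathway"  # or "per_curve"
    ka_policy: str = "fix_to_binding"  # or "fit"
    alpha: float = Field(default=0.05, gt=0, lt=1)
    fold_bins: Sequence[float] = (3.0, 5.0, 10.0, 30.0)
    average_duplicates: bool = True
    fix_bottom: Optional[float] = None
    seed: int = 0

    @field_validator("em_policy")
    @classmethod
    def _em_policy(cls, v: str) -> str:
        if v not in {"shared_per_pathway", "per_curve"}:
            raise ValueError(f"unknown em_policy {v!r}")
        return v

    @field_validator("ka_policy")
    @classmethod
    def _ka_policy(cls, v: str) -> str:
        if v not in {"fit", "fix_to_binding"}:
            raise ValueError(f"unknown ka_policy {v!r}")
        return v

    @model_validator(mode="after")
    def _bins_increasing(self) -> "RunConfig":
        bins = list(self.fold_bins)
        if any(b <= 1 for b in bins):
            raise ValueError("fold_bins must all exceed 1")
        if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
            raise ValueError("fold_bins must be strictly increasing")
        return self


# --------------------------------------------------------------------------
# validation report
# --------------------------------------------------------------------------

@dataclass
class ValidationIssue:
    row: Optional[int]
    column: Optional[str]
    message: str
    action: str  # "flagged", "dropped", "error"


@dataclass
class ValidationReport:
    table_kind: str = ""
    n_rows_in: int = 0
    n_rows_out: int = 0
    issues: list = field(default_factory=list)

    def add(self, row, column, message, action="flagged") -> None:
        self.issues.append(ValidationIssue(row, column, message, action))

    @property
    def n_flagged(self) -> int:
        return sum(1 for i in self.issues if i.action in ("flagged", "dropped"))

    def __bool__(self) -> bool:  # truthy when clean
        return not self.issues
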