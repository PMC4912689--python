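"""Synthetic study generator with known ground truth.

Emulates the full experimental design end to end — three peptide ligands
(GLP-1, oxyntomodulin, exendin-4) assayed at three signaling pathways
(cAMP accumulation, ERK1/2 phosphorylation, intracellular Ca2+
mobilization) for a wild-type receptor and alanine point mutants, with
five independent experiments conducted in duplicate by default.

Generative law: functional responses are drawn as operational-model means
times (1 + N(0, cv)) (multiplicative, constant-CV plate-reader noise), with
a small per-experiment random effect on the system maximum so that
per-experiment fitting and SEM pooling are exercised honestly. Competition
binding curves come from one-site displacement around the true pKi with
additive noise in % units (so values may stray slightly outside [0, 100],
as nonspecific-subtracted data do). Cell-surface expression measurements
are drawn around the true fraction with a 5% relative SEM.

Receptor density scales efficacy: curves are generated with an *effective*
log tau = intrinsic log tau + log10(expression fraction). Recovering the
intrinsic value is exactly what the tau_c expression correction is for, so
the expression-deficit scenario is a genuine recovery test, not a tautology.

Every dataset is reproducible: the same seed yields byte-identical CSVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import write_results, write_json
from .operational import operational_response

__all__ = [
    "NoiseModel", "TruthPanel", "SimulatedDataset",
    "default_grid", "default_binding_grid",
    "wild_type_truth", "scenario_library", "generate_panel",
    "make_synthetic_structure",
]

LIGANDS = ("GLP-1", "oxyntomodulin", "exendin-4")
PATHWAYS = ("cAMP", "pERK", "iCa")

#: wild-type ground truth: binding affinity pKi per ligand (log K_A = -pKi,
#: i.e. functional and binding affinity agree for these agonists)
WT_PKI = {"GLP-1": 8.0, "oxyntomodulin": 7.0, "exendin-4": 8.5}

#: wild-type intrinsic log tau per (ligand, pathway). The oxyntomodulin pERK
#: value encodes its built-in pathway bias: its transduction coefficients
#: give DeltaDelta log(tau/K_A) = +1.0 toward pERK vs GLP-1/cAMP (a 10-fold
#: bias factor), while exendin-4 is unbiased. Its iCa efficacy is set so low
#: that the pathway yields no measurable response, mirroring why that
#: pathway is only assessed for the other two peptides.
WT_LOG_TAU = {
    ("GLP-1", "cAMP"): 0.7, ("exendin-4", "cAMP"): 1.0, ("oxyntomodulin", "cAMP"): 0.0,
    ("GLP-1", "pERK"): 0.4, ("exendin-4", "pERK"): 0.7, ("oxyntomodulin", "pERK"): 0.7,
    ("GLP-1", "iCa"): 0.5, ("exendin-4", "iCa"): 0.8, ("oxyntomodulin", "iCa"): -2.0,
}

WT_EM = 100.0
WT_BOTTOM = 0.0

TRACER_KD = 1e-9
TRACER_CONC = 5e-10


def default_grid(n_points: int = 10) -> np.ndarray:
    """Agonist concentration grid: log-even points spanning 1 pM - 1 uM."""
    return np.logspace(-12.0, -6.0, n_points)


def default_binding_grid(n_points: int = 10) -> np.ndarray:
    """Competitor log10 molar grid for displacement curves."""
    return np.linspace(-11.0, -5.0, n_points)


@dataclass
class NoiseModel:
    """Measurement-noise and replication settings of the simulated study."""

    cv: float = 0.05                   # fractional Gaussian noise on responses
    n_experiments: int = 5             # independent experiments (design: 4-6)
    n_duplicates: int = 2              # technical duplicates per experiment
    experiment_effect_sd: float = 0.05  # between-day shift in the system maximum
    expression_rel_sem: float = 0.05   # relative SEM of the expression assay
    binding_sd: float = 5.0            # additive noise on % specific binding
    additive: bool = False             # additive response noise (sd = cv * Em)
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_experiments < 1 or self.n_duplicates < 1:
            raise ValueError("need >= 1 experiment and duplicate")


@dataclass
class TruthPanel:
    """Ground truth for one simulated study.

    ``functional`` holds intrinsic log tau / log K_A / Em / Bottom per
    construct x ligand x pathway; ``binding`` true pKi per construct x
    ligand; ``expression`` the true surface-expression fraction (NaN with
    status not_determined for dead-surface constructs); ``constructs`` the
    panel metadata.
    """

    name: str
    functional: pd.DataFrame
    binding: pd.DataFrame
    expression: pd.DataFrame
    constructs: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "functional": self.functional.to_dict("records"),
            "binding": self.binding.to_dict("records"),
            "expression": self.expression.to_dict("records"),
            "constructs": self.constructs.to_dict("records"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthPanel":
        return cls(name=d["name"],
                   functional=pd.DataFrame(d["functional"]),
                   binding=pd.DataFrame(d["binding"]),
                   expression=pd.DataFrame(d["expression"]),
                   constructs=pd.DataFrame(d["constructs"]))


@dataclass
class SimulatedDataset:
    """Generated input tables plus the truth they were drawn from."""

    response: pd.DataFrame
    binding: pd.DataFrame
    expression: pd.DataFrame
    truth: TruthPanel
    noise: NoiseModel

    def write(self, outdir: Union[str, Path]) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "response": write_results(self.response, outdir / "response.csv"),
            "binding": write_results(self.binding, outdir / "binding.csv"),
            "expression": write_results(self.expression, outdir / "expression.csv"),
            "truth": write_json(self.truth.to_dict(), outdir / "truth.json"),
        }
        return paths


# --------------------------------------------------------------------------
# truth construction
# --------------------------------------------------------------------------

def _region_of(position: int) -> str:
    if 201 <= position <= 223:
        return "ECL1"
    if 285 <= position <= 307:
        return "ECL2"
    if 372 <= position <= 387:
        return "ECL3"
    return "other"


def _construct_row(cid: str, scenario: str) -> dict:
    if cid == "WT":
        return dict(construct_id="WT", kind="wild_type", position=None,
                    wt_residue=None, mut_residue=None, region="other",
                    scenario=scenario)
    wt_res, pos = cid[0], int(cid[1:-1])
    return dict(construct_id=cid, kind="point_mutant", position=pos,
                wt_residue=wt_res, mut_residue="A", region=_region_of(pos),
                scenario=scenario)


def wild_type_truth(ligands: Sequence[str] = LIGANDS,
                    pathways: Sequence[str] = PATHWAYS) -> TruthPanel:
    """TruthPanel containing only the wild-type receptor."""
    return _build_truth("baseline", {"WT": {}}, ligands, pathways)


def _build_truth(name: str, mutants: Mapping[str, dict],
                 ligands: Sequence[str], pathways: Sequence[str]) -> TruthPanel:
    """Assemble a TruthPanel from per-construct modifications of the WT truth.

    Each construct's spec dict may contain ``tau_fold`` (scalar, or map
    ``ligand`` or ``(ligand, pathway)`` -> multiplicative factor on tau),
    ``pki_shift`` (scalar or map ligand -> log10 shift, applied to both pKi
    and log K_A), ``expression`` (fraction of wild-type, None for a
    dead-surface construct) and ``scenario`` (tag).
    """
    func_rows, bind_rows, expr_rows, cons_rows = [], [], [], []
    for cid, spec in mutants.items():
        scenario = spec.get("scenario", "wild_type" if cid == "WT" else "mutant")
        cons_rows.append(_construct_row(cid, scenario))
        expr = spec.get("expression", 1.0)
        expr_rows.append(dict(construct_id=cid,
                              expression_fraction=np.nan if expr is None else float(expr),
                              status="not_determined" if expr is None else "ok"))
        for lig in ligands:
            shift = spec.get("pki_shift", 0.0)
            if isinstance(shift, Mapping):
                shift = shift.get(lig, 0.0)
            pki = WT_PKI[lig] - float(shift)
            bind_rows.append(dict(construct_id=cid, ligand_id=lig, pki=pki))
            for pw in pathways:
                fold = spec.get("tau_fold", 1.0)
                if isinstance(fold, Mapping):
                    fold = fold.get((lig, pw), fold.get(lig, 1.0))
                log_tau = WT_LOG_TAU[(lig, pw)] + np.log10(float(fold))
                func_rows.append(dict(
                    construct_id=cid, ligand_id=lig, pathway_id=pw,
                    log_tau=log_tau, log_ka=-pki, em=WT_EM, bottom=WT_BOTTOM,
                    scenario=scenario))
    return TruthPanel(
        name=name,
        functional=pd.DataFrame(func_rows),
        binding=pd.DataFrame(bind_rows),
        expression=pd.DataFrame(expr_rows),
        constructs=pd.DataFrame(cons_rows),
    )


def scenario_library() -> Dict[str, TruthPanel]:
    """Named TruthPanels covering the study's phenotype classes.

    * ``baseline`` — wild-type receptor, all three peptides, all pathways
      (GLP-1-like full-agonist panel).
    * ``oxyntomodulin_bias`` — wild-type panel restricted to cAMP and pERK;
      the truth encodes oxyntomodulin's 10-fold pERK bias factor.
    * ``efficacy_ladder`` — cAMP-efficacy losses of 4x, 7x, 18x and an
      effectively dead (>30x) coupling mutant.
    * ``affinity_ladder`` — pKi losses of 0.60, 0.85, 1.25 and 1.60 log
      units (4x to 40x).
    * ``expression_deficit`` — surface expression at 0.3 of wild-type with
      intrinsic tau unchanged (the tau_c contract scenario).
    * ``enhanced_efficacy`` — a pERK-enhancing mutant for GLP-1/exendin-4
      with the opposite (reducing) effect on oxyntomodulin.
    * ``dead_surface`` — a construct with no measurable surface expression
      (not_determined throughout).
    * ``full_panel`` — all of the above in one dataset.
    """
    eff = {
        "WT": {},
        "Y205A": {"tau_fold": 1 / 4.0, "scenario": "efficacy_loss_3_5"},
        "R299A": {"tau_fold": 1 / 7.0, "scenario": "efficacy_loss_5_10"},
        "E294A": {"tau_fold": 1 / 18.0, "scenario": "efficacy_loss_10_30"},
        "W297A": {"tau_fold": 1 / 100.0, "scenario": "efficacy_loss_gt_30"},
    }
    aff = {
        "WT": {},
        "L218A": {"pki_shift": 0.60, "scenario": "affinity_loss_3_5"},
        "K288A": {"pki_shift": 0.85, "scenario": "affinity_loss_5_10"},
        "D293A": {"pki_shift": 1.25, "scenario": "affinity_loss_10_30"},
        "K383A": {"pki_shift": 1.60, "scenario": "affinity_loss_gt_30"},
    }
    expr = {
        "WT": {},
        "N300A": {"expression": 0.3, "scenario": "expression_deficit"},
    }
    enh = {
        "WT": {},
        "T378A": {"tau_fold": {("GLP-1", "pERK"): 5.0,
                               ("exendin-4", "pERK"): 5.0,
                               ("oxyntomodulin", "pERK"): 1 / 5.0},
                  "scenario": "enhanced_efficacy"},
    }
    dead = {
        "WT": {},
        "W306A": {"expression": None, "scenario": "dead_surface"},
    }
    full = {}
    for d in (eff, aff, expr, enh, dead):
        full.update({k: dict(v) for k, v in d.items()})
    return {
        "baseline": _build_truth("baseline", {"WT": {}}, LIGANDS, PATHWAYS),
        "oxyntomodulin_bias": _build_truth("oxyntomodulin_bias", {"WT": {}},
                                           LIGANDS, ("cAMP", "pERK")),
        "efficacy_ladder": _build_truth("efficacy_ladder", eff, LIGANDS, ("cAMP",)),
        "affinity_ladder": _build_truth("affinity_ladder", aff, LIGANDS, ("cAMP",)),
        "expression_deficit": _build_truth("expression_deficit", expr,
                                           ("GLP-1", "oxyntomodulin"), ("cAMP",)),
        "enhanced_efficacy": _build_truth("enhanced_efficacy", enh, LIGANDS, ("pERK",)),
        "dead_surface": _build_truth("dead_surface", dead, LIGANDS, ("cAMP",)),
        "full_panel": _build_truth("full_panel", full, LIGANDS, PATHWAYS),
    }


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def generate_panel(truth: TruthPanel, noise: Optional[NoiseModel] = None,
                   grid: Optional[np.ndarray] = None,
                   binding_grid: Optional[np.ndarray] = None,
                   tracer_kd: float = TRACER_KD,
                   tracer_conc: float = TRACER_CONC) -> SimulatedDataset:
    """Draw a complete synthetic dataset from a TruthPanel.

    Returns the three input tables (concentration-response, competition
    binding, cell-surface expression) together with the truth. Deterministic
    under ``noise.seed``. Warns when the concentration grid does not cover
    EC50 +/- 1 log unit for some active curve.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    binding_grid = (default_binding_grid() if binding_grid is None
                    else np.asarray(binding_grid, dtype=float))
    if np.unique(grid[grid > 0]).size < 6:
        raise ValueError("concentration grid needs >= 6 distinct non-zero points")

    expr_lookup = truth.expression.set_index("construct_id")

    # grid-coverage check on active curves
    lo, hi = np.log10(grid.min()), np.log10(grid.max())
    for r in truth.functional.itertuples():
        expr = expr_lookup.loc[r.construct_id, "expression_fraction"]
        if not np.isfinite(expr):
            continue
        tau = 10.0 ** (r.log_tau + np.log10(expr))
        if tau < 0.05:  # no measurable window: coverage is irrelevant
            continue
        pec50 = -r.log_ka + np.log10(tau + 1.0)
        if not (lo + 1.0 <= -pec50 <= hi - 1.0):
            warnings.warn(
                f"grid does not cover EC50 +/- 1 log for "
                f"{r.construct_id}/{r.ligand_id}/{r.pathway_id} (pEC50 {pec50:.2f})",
                stacklevel=2)

    # --- functional responses -------------------------------------------
    conc_points = np.concatenate([[0.0], grid])  # basal wells anchor Bottom
    resp_rows = []
    func = truth.functional.sort_values(
        ["construct_id", "pathway_id", "ligand_id"]).reset_index(drop=True)
    for (construct, pathway), block in func.groupby(["construct_id", "pathway_id"],
                                                    sort=True):
        expr = expr_lookup.loc[construct, "expression_fraction"]
        for exp_id in range(1, noise.n_experiments + 1):
            day_effect = 1.0 + rng.normal(0.0, noise.experiment_effect_sd)
            for r in block.itertuples():
                em_e = r.em * day_effect
                if np.isfinite(expr):
                    eff_log_tau = r.log_tau + np.log10(expr)
                    mean = operational_response(conc_points, eff_log_tau,
                                                r.log_ka, em_e, r.bottom)
                else:  # no surface receptor: flat at baseline
                    mean = np.full(conc_points.shape, r.bottom)
                for rep in range(1, noise.n_duplicates + 1):
                    if noise.additive:
                        obs = mean + rng.normal(0.0, noise.cv * r.em, mean.size)
                    else:
                        obs = mean * (1.0 + rng.normal(0.0, noise.cv, mean.size))
                    for c, y in zip(conc_points, obs):
                        resp_rows.append((construct, r.ligand_id, pathway,
                                          exp_id, rep, c, y))
    response = pd.DataFrame(resp_rows, columns=[
        "construct_id", "ligand_id", "pathway_id", "experiment_id",
        "replicate_id", "concentration", "response"])

    # --- competition binding --------------------------------------------
    correction = np.log10(1.0 + tracer_conc / tracer_kd)
    bind_rows = []
    bind = truth.binding.sort_values(["construct_id", "ligand_id"]).reset_index(drop=True)
    for r in bind.itertuples():
        expr = expr_lookup.loc[r.construct_id, "expression_fraction"]
        pic50 = r.pki - correction
        for exp_id in range(1, noise.n_experiments + 1):
            if np.isfinite(expr):
                mean = 100.0 / (1.0 + 10.0 ** (binding_grid + pic50))
            else:  # no receptor, no specific binding
                mean = np.zeros(binding_grid.shape)
            obs = mean + rng.normal(0.0, noise.binding_sd, mean.size)
            for lc, y in zip(binding_grid, obs):
                bind_rows.append((r.construct_id, r.ligand_id, exp_id, lc, y))
    binding = pd.DataFrame(bind_rows, columns=[
        "construct_id", "ligand_id", "experiment_id", "log_conc", "specific_binding"])

    # --- cell-surface expression ----------------------------------------
    expr_rows = []
    for r in truth.expression.sort_values("construct_id").itertuples():
        if r.status == "not_determined" or not np.isfinite(r.expression_fraction):
            expr_rows.append((r.construct_id, np.nan, np.nan, "not_determined"))
            continue
        obs = r.expression_fraction * (1.0 + rng.normal(0.0, noise.expression_rel_sem))
        obs = max(obs, 1e-3)
        expr_rows.append((r.construct_id, obs, noise.expression_rel_sem * obs, "ok"))
    expression = pd.DataFrame(expr_rows, columns=[
        "construct_id", "expression_fraction", "sem", "status"])

    return SimulatedDataset(response=response, binding=binding,
                            expression=expression, truth=truth, noise=noise)


# --------------------------------------------------------------------------
# synthetic structure
# --------------------------------------------------------------------------

def make_synthetic_structure(positions: Sequence[int],
                             path: Optional[Union[str, Path]] = None):
    """Build a synthetic CA-only PDB structure covering the given residues.

    This is a stand-in geometry (an ideal helix trace of alanines), not a
    receptor model: it exists so that annotation export and round-trip can
    be exercised without any deposited structure. Returns the biotite
    AtomArray; also writes a PDB file when ``path`` is given.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    positions = sorted(int(p) for p in positions)
    n = len(positions)
    atoms = struc.AtomArray(n)
    t = np.arange(n, dtype=float)
    coords = np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * t], axis=1)
    atoms.coord = coords
    atoms.res_id = np.array(positions, dtype=int)
    atoms.res_name = np.array(["ALA"] * n)
    atoms.atom_name = np.array(["CA"] * n)
    atoms.element = np.array(["C"] * n)
    atoms.chain_id = np.array(["A"] * n)
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.set_annotation("b_factor", np.zeros(n))
    if path is not None:
        pdb = PDBFile()
        pdb.set_structure(atoms)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        pdb.write(str(path))
    return atoms
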