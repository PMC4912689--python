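"""Residue-level structural annotation of mutational effects.

Maps scanned residue positions to receptor regions (the extracellular loops
and their transmembrane boundaries), summarizes per-ligand heat categories
into cross-ligand classes (globally important, ligand-selective, shared by
two, enhanced, mixed), and exports the annotation as a B-factor-encoded PDB
plus a companion TSV so any molecular viewer can render the heatmap.

The bundled region defaults are the loop spans of the scanned receptor:
ECL1 (with its TM boundaries) 201-223, ECL2 285-307, ECL3 372-387; residue
numbering is 1-based protein-sequence numbering throughout. Class-B
"Wootten" numbers are attached from a user-supplied lookup table when
available, never computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile

from .datamodel import CATEGORY_COLORS, HEAT_CATEGORY_BY_CODE, HeatCategory, SummaryClass
from .io import write_json

__all__ = [
    "RegionDefinition", "DEFAULT_REGIONS", "assign_regions",
    "summarize_across_ligands", "summarize_table",
    "write_structure_annotation", "read_structure_annotation", "write_legend",
]

#: B-factor value given to residues outside the annotation set
SENTINEL_BFACTOR = -9.99


@dataclass(frozen=True)
class RegionDefinition:
    name: str
    start: int
    end: int  # inclusive

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"region {self.name}: end < start")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


DEFAULT_REGIONS = (
    RegionDefinition("ECL1", 201, 223),
    RegionDefinition("ECL2", 285, 307),
    RegionDefinition("ECL3", 372, 387),
)


def _validate_regions(regions: Sequence[RegionDefinition]) -> None:
    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            if a.start <= b.end and b.start <= a.end:
                raise ValueError(f"regions {a.name} and {b.name} overlap")


def assign_regions(positions: Iterable[int],
                   regions: Sequence[RegionDefinition] = DEFAULT_REGIONS,
                   ) -> pd.DataFrame:
    """Map residue positions to regions ("other" outside every span).

    Returns a frame with columns ``position, region``; per-region residue
    counts (over the full spans, not just the queried positions) are stored
    in ``attrs["region_sizes"]``.
    """
    regions = list(regions)
    _validate_regions(regions)
    rows = []
    for pos in positions:
        pos = int(pos)
        if pos < 1:
            raise ValueError(f"residue position must be >= 1, got {pos}")
        name = next((r.name for r in regions if pos in r), "other")
        rows.append({"position": pos, "region": name})
    out = pd.DataFrame(rows, columns=["position", "region"])
    out.attrs["region_sizes"] = {r.name: len(r) for r in regions}
    return out


_REDUCED = {HeatCategory.fold_3_5, HeatCategory.fold_5_10,
            HeatCategory.fold_10_30, HeatCategory.fold_gt_30}


def summarize_across_ligands(categories: Mapping[str, HeatCategory]) -> SummaryClass:
    """Collapse per-ligand heat categories of one residue into a summary class.

    Rules (order matters): opposite directions coexisting -> mixed; any
    enhancement with no reduction -> enhanced; every assessed ligand reduced
    (two or more assessed) -> global_all_ligands; exactly one / two ligands
    reduced -> selective_single_ligand / shared_two_ligands; otherwise none.
    Ligands with category not_determined are not counted as assessed.
    The result is invariant to ligand order.
    """
    assessed = {l: HeatCategory(c) for l, c in categories.items()
                if HeatCategory(c) is not HeatCategory.not_determined}
    if not assessed:
        return SummaryClass.none
    reduced = [l for l, c in assessed.items() if c in _REDUCED]
    enhanced = [l for l, c in assessed.items() if c is HeatCategory.enhanced]
    if reduced and enhanced:
        return SummaryClass.mixed
    if enhanced:
        return SummaryClass.enhanced
    if reduced:
        if len(reduced) == len(assessed) and len(assessed) >= 2:
            return SummaryClass.global_all_ligands
        if len(reduced) == 1:
            return SummaryClass.selective_single_ligand
        if len(reduced) == 2:
            return SummaryClass.shared_two_ligands
        return SummaryClass.global_all_ligands
    return SummaryClass.none


def summarize_table(heat: pd.DataFrame,
                    regions: Sequence[RegionDefinition] = DEFAULT_REGIONS,
                    wootten: Optional[Mapping[int, str]] = None) -> pd.DataFrame:
    """Per-residue annotation table from a classified heat table.

    ``heat`` needs columns ``position, ligand_id, category`` (one measure at
    a time). Returns one row per position with its region, optional Wootten
    number, per-ligand categories (columns ``category_<ligand>``) and the
    cross-ligand ``summary_class``.
    """
    rows = []
    for pos, g in heat.groupby("position"):
        cats = {str(r.ligand_id): HeatCategory(r.category) for r in g.itertuples()}
        row = {"position": int(pos)}
        for lig, c in sorted(cats.items()):
            row[f"category_{lig}"] = c.value
        row["summary_class"] = summarize_across_ligands(cats).value
        rows.append(row)
    out = pd.DataFrame(rows)
    reg = assign_regions(out["position"], regions)
    out = out.merge(reg, on="position")
    if wootten:
        out["wootten_number"] = out["position"].map(dict(wootten))
    return out.sort_values("position").reset_index(drop=True)


# --------------------------------------------------------------------------
# PDB export
# --------------------------------------------------------------------------

def _as_category_map(annotations) -> Dict[int, HeatCategory]:
    if isinstance(annotations, pd.DataFrame):
        return {int(r.position): HeatCategory(r.category) for r in annotations.itertuples()}
    return {int(k): HeatCategory(v) for k, v in dict(annotations).items()}


def write_structure_annotation(annotations, structure_path: Union[str, Path],
                               out_pdb: Union[str, Path],
                               out_tsv: Optional[Union[str, Path]] = None,
                               offset: int = 0,
                               regions: Sequence[RegionDefinition] = DEFAULT_REGIONS,
                               max_missing_frac: float = 0.2):
    """Write heat categories into the B-factor column of a PDB structure.

    Every atom of an annotated residue gets its category code (0 no_effect
    ... 4 fold_gt_30, 5 enhanced, -1 not_determined); all other residues get
    the sentinel value. ``offset`` is added to annotation positions to match
    the structure's residue numbering. Annotated positions absent from the
    structure trigger a warning listing them; when more than
    ``max_missing_frac`` of positions are missing the numbering is assumed
    wrong and a hard error suggests adjusting the offset.

    Returns ``(out_pdb_path, tsv_path_or_None)``. The companion TSV lists
    position, region, category and code for each annotated residue.
    """
    categories = _as_category_map(annotations)
    pdb = PDBFile.read(str(structure_path))
    atoms = pdb.get_structure(model=1, extra_fields=["b_factor"])

    res_ids = set(int(i) for i in np.unique(atoms.res_id))
    missing = sorted(p for p in categories if p + offset not in res_ids)
    if categories and len(missing) > max_missing_frac * len(categories):
        raise ValueError(
            f"{len(missing)}/{len(categories)} annotated positions are absent from the "
            f"structure (e.g. {missing[:5]}); residue numbering likely mismatched — "
            f"try a different offset (current offset={offset})")
    if missing:
        warnings.warn(f"positions missing from structure: {missing}", stacklevel=2)

    b = np.full(atoms.array_length(), SENTINEL_BFACTOR)
    for pos, cat in categories.items():
        b[atoms.res_id == pos + offset] = float(cat.code)
    atoms.set_annotation("b_factor", b)

    out = PDBFile()
    out.set_structure(atoms)
    out_pdb = Path(out_pdb)
    out_pdb.parent.mkdir(parents=True, exist_ok=True)
    out.write(str(out_pdb))

    tsv_path = None
    if out_tsv is not None:
        reg = assign_regions(sorted(categories), regions).set_index("position")
        rows = [{"position": p, "region": reg.loc[p, "region"],
                 "category": categories[p].value, "code": categories[p].code}
                for p in sorted(categories)]
        tsv_path = Path(out_tsv)
        tsv_path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows, columns=["position", "region", "category", "code"]).to_csv(
            tsv_path, sep="\t", index=False)
    return out_pdb, tsv_path


def read_structure_annotation(pdb_path: Union[str, Path]) -> Dict[int, HeatCategory]:
    """Recover the per-residue heat categories from an annotated PDB.

    Residues carrying the sentinel B-factor are skipped; others are decoded
    from the (rounded) B-factor back to their :class:`HeatCategory`.
    """
    pdb = PDBFile.read(str(pdb_path))
    atoms = pdb.get_structure(model=1, extra_fields=["b_factor"])
    out: Dict[int, HeatCategory] = {}
    for res_id in np.unique(atoms.res_id):
        bf = atoms.b_factor[atoms.res_id == res_id]
        code = int(round(float(bf[0])))
        if abs(float(bf[0]) - SENTINEL_BFACTOR) < 1e-6:
            continue
        if code in HEAT_CATEGORY_BY_CODE:
            out[int(res_id)] = HEAT_CATEGORY_BY_CODE[code]
    return out


def write_legend(path: Union[str, Path]) -> Path:
    """Ship the category -> color legend (published color convention) as JSON."""
    legend = {cat.value: {"code": cat.code, "color": color}
              for cat, color in CATEGORY_COLORS.items()}
    return write_json(legend, path)
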