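"""Cα structure reading/writing and residue-level bookkeeping.

The whole pipeline works at Cα resolution: a structure is an ordered list of
residue identifiers plus an N×3 coordinate matrix in Å.  Two end states are
joined through a :class:`ResidueMapping`, whose pair list defines the common
working index set used by every downstream module.

PDB reading goes through Bio.PDB; only ATOM records with atom name CA are
kept (HETATM and waters are ignored), and alternate locations resolve to the
highest-occupancy record (ties keep the first encountered).  Multi-model
pathway output is written as one MODEL/ENDMDL block per conformer with
CA-only ATOM records at standard PDB precision (3 decimals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .errors import MappingError, PdbParseError

__all__ = [
    "ResidueId",
    "CaStructure",
    "ResidueMapping",
    "parse_residue_spec",
    "read_ca_structure",
    "read_residue_map",
    "map_common_residues",
    "write_path_pdb",
    "write_analysis_table",
]


class ResidueId(NamedTuple):
    """PDB author identification of one residue (insertion codes honoured)."""

    chain: str
    number: int
    icode: str
    name: str

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity used for mapping: (chain, number, insertion code)."""
        return (self.chain, self.number, self.icode)

    def spec(self) -> str:
        s = f"{self.chain}:{self.number}"
        return f"{s}:{self.icode}" if self.icode else s


@dataclass
class CaStructure:
    """Ordered Cα residues with coordinates in Å.

    Row ``i`` of :attr:`coords` belongs to ``residues[i]``.  Residue keys
    (chain, number, icode) must be unique and all coordinates finite.
    """

    residues: list[ResidueId]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be N×3, got {self.coords.shape}")
        if len(self.residues) != self.coords.shape[0]:
            raise ValueError("residues and coords length mismatch")
        if len(self.residues) < 1:
            raise ValueError("structure must contain at least one residue")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue identifiers")

    def __len__(self) -> int:
        return len(self.residues)

    def index_of(self, key: tuple[str, int, str]) -> int:
        try:
            return self._key_index[key]
        except AttributeError:
            self._key_index = {r.key: i for i, r in enumerate(self.residues)}
            return self._key_index[key]

    def subset(self, indices: Sequence[int]) -> "CaStructure":
        idx = list(indices)
        return CaStructure([self.residues[i] for i in idx], self.coords[idx])


@dataclass
class ResidueMapping:
    """Pairing of residue indices between structures A and B.

    ``pairs[k] = (i_a, i_b)`` means row ``i_a`` of A corresponds to row
    ``i_b`` of B.  Each index appears at most once; pairs are sorted by the
    A index.
    """

    pairs: np.ndarray

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be K×2")
        if self.pairs.shape[0] < 1:
            raise MappingError("empty residue mapping")
        for col in (0, 1):
            vals = self.pairs[:, col]
            if len(np.unique(vals)) != len(vals):
                raise MappingError("a residue index appears more than once")
        order = np.argsort(self.pairs[:, 0], kind="stable")
        self.pairs = self.pairs[order]

    @property
    def n_common(self) -> int:
        return self.pairs.shape[0]

    @property
    def a_indices(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def b_indices(self) -> np.ndarray:
        return self.pairs[:, 1]

    def swapped(self) -> "ResidueMapping":
        return ResidueMapping(self.pairs[:, ::-1].copy())


def parse_residue_spec(spec: str) -> tuple[str, int, str]:
    """Parse ``chain:resnum[:icode]`` into a residue key."""
    parts = spec.strip().split(":")
    if len(parts) not in (2, 3) or not parts[0]:
        raise MappingError(f"bad residue spec {spec!r}; expected chain:resnum[:icode]")
    try:
        number = int(parts[1])
    except ValueError as exc:
        raise MappingError(f"bad residue number in spec {spec!r}") from exc
    icode = parts[2] if len(parts) == 3 else ""
    return (parts[0], number, icode)


def read_ca_structure(
    path: str | Path,
    chain_filter: Iterable[str] | None = None,
    model_index: int = 0,
) -> CaStructure:
    """Read one model of a PDB file as a Cα structure.

    Parameters
    ----------
    path:
        PDB file with at least one CA ATOM record in the selected model.
    chain_filter:
        Optional set of chain identifiers to keep.
    model_index:
        Which MODEL block to read (0-based; 0 also reads single-model files).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise PdbParseError(f"{path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise PdbParseError(f"{path}: file contains no models")
    if model_index < 0 or model_index >= len(models):
        raise PdbParseError(
            f"{path}: model index {model_index} out of range (have {len(models)})"
        )
    keep = set(chain_filter) if chain_filter is not None else None
    residues: list[ResidueId] = []
    coords: list[np.ndarray] = []
    for chain in models[model_index]:
        if keep is not None and chain.id not in keep:
            continue
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip():
                continue  # HETATM / water
            if "CA" not in res:
                continue
            atom = res["CA"]  # disordered atom resolves to top occupancy
            residues.append(
                ResidueId(chain.id, resseq, icode.strip(), res.resname.strip())
            )
            coords.append(np.asarray(atom.get_coord(), dtype=float))
    if not residues:
        raise PdbParseError(f"{path}: no CA atoms after filtering")
    return CaStructure(residues, np.vstack(coords))


def read_ca_trajectory(
    path: str | Path, chain_filter: Iterable[str] | None = None
) -> list[CaStructure]:
    """Read every model of a multi-model PDB file (single parse)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise PdbParseError(f"{path}: {exc}") from exc
    keep = set(chain_filter) if chain_filter is not None else None
    out: list[CaStructure] = []
    for model in structure:
        residues: list[ResidueId] = []
        coords: list[np.ndarray] = []
        for chain in model:
            if keep is not None and chain.id not in keep:
                continue
            for res in chain:
                hetflag, resseq, icode = res.id
                if hetflag.strip() or "CA" not in res:
                    continue
                residues.append(
                    ResidueId(chain.id, resseq, icode.strip(), res.resname.strip())
                )
                coords.append(np.asarray(res["CA"].get_coord(), dtype=float))
        if residues:
            out.append(CaStructure(residues, np.vstack(coords)))
    if not out:
        raise PdbParseError(f"{path}: no CA atoms in any model")
    return out


def read_residue_map(path: str | Path) -> list[tuple[str, str]]:
    """Read an explicit two-column mapping file.

    One pair per line, columns separated by whitespace or a comma; residues
    written as ``chain:resnum[:icode]``.  Blank lines and ``#`` comments are
    skipped.
    """
    out: list[tuple[str, str]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        cols = text.replace(",", " ").split()
        if len(cols) != 2:
            raise MappingError(f"{path}: line {ln}: expected two columns, got {len(cols)}")
        out.append((cols[0], cols[1]))
    return out


def map_common_residues(
    a: CaStructure,
    b: CaStructure,
    explicit_map: Sequence[tuple[str, str]] | None = None,
) -> ResidueMapping:
    """Establish the common-residue index set between two end states.

    Default mode pairs residues with identical (chain, number, insertion
    code).  ``explicit_map`` overrides this with a verbatim two-column list of
    residue specs — needed when the two states use shifted author numbering
    over structurally corresponding regions (the P-gp usage, where the
    inward-facing model spans 34–630/701–1275 and the outward-facing one
    36–631/697–1276).
    """
    if explicit_map is None:
        b_index = {r.key: i for i, r in enumerate(b.residues)}
        pairs = [
            (i, b_index[r.key]) for i, r in enumerate(a.residues) if r.key in b_index
        ]
        if not pairs:
            raise MappingError("no residues with identical identifiers in A and B")
        return ResidueMapping(np.array(pairs, dtype=int))
    pairs = []
    for spec_a, spec_b in explicit_map:
        key_a = parse_residue_spec(spec_a)
        key_b = parse_residue_spec(spec_b)
        try:
            ia = a.index_of(key_a)
        except KeyError as exc:
            raise MappingError(f"residue {spec_a} absent from structure A") from exc
        try:
            ib = b.index_of(key_b)
        except KeyError as exc:
            raise MappingError(f"residue {spec_b} absent from structure B") from exc
        pairs.append((ia, ib))
    if not pairs:
        raise MappingError("explicit mapping is empty")
    return ResidueMapping(np.array(pairs, dtype=int))


def _format_ca_record(serial: int, res: ResidueId, xyz: np.ndarray) -> str:
    # fixed-column PDB ATOM record, CA only
    icode = res.icode if res.icode else " "
    return (
        f"ATOM  {serial:5d}  CA  {res.name:>3.3s} {res.chain[:1]:1s}"
        f"{res.number:4d}{icode:1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"  1.00  0.00           C"
    )


def write_path_pdb(path, structure_template: CaStructure, out: str | Path) -> None:
    """Write an ordered conformer series as a multi-model CA-only PDB file.

    ``path`` may be a TransitionPath, a list of conformers, or a list of
    N×3 coordinate arrays.  Every conformer must match the template's residue
    count; residue metadata comes from the template.
    """
    conformers = getattr(path, "conformers", path)
    coord_sets = [np.asarray(getattr(c, "coords", c), dtype=float) for c in conformers]
    n = len(structure_template)
    for k, xyz in enumerate(coord_sets):
        if xyz.shape != (n, 3):
            raise ValueError(
                f"conformer {k} has shape {xyz.shape}, template has {n} residues"
            )
    lines: list[str] = []
    for m, xyz in enumerate(coord_sets, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, res in enumerate(structure_template.residues):
            lines.append(_format_ca_record(i + 1, res, xyz[i]))
        lines.append("ENDMDL")
    lines.append("END")
    Path(out).write_text("\n".join(lines) + "\n")


def write_analysis_table(records, out: str | Path) -> None:
    """Write tabular analysis output as CSV (header + one row per record).

    ``records`` is a DataFrame or a list of dicts with a uniform column set;
    ragged rows are rejected.  Floats are written at full repr precision with
    a locale-independent decimal point, so a round-trip read reproduces values
    to well below 1e-9.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records:
            cols = list(records[0].keys())
            for k, row in enumerate(records):
                if list(row.keys()) != cols:
                    raise ValueError(f"row {k} has a different column set")
            df = pd.DataFrame(records, columns=cols)
        else:
            df = pd.DataFrame()
    df.to_csv(out, index=False)
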