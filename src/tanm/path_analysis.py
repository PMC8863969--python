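"""Pathway diagnostics.

Given a transition path these functions compute the scalar reaction
coordinate, the energy profile on both surfaces, residue-pair Cα distances,
the acute angle between two residue-defined line segments (a twist monitor
for domain pairs such as the two nucleotide-binding domains of an ABC
exporter), per-conformer RMSD against an external reference structure, and
cosine cross-correlation maps of residue displacements.

The reaction coordinate of conformer R(n) is the projection of its cumulative
displacement onto the end-to-end displacement:

    x(n) = d⁽⁰⁾ · v(n) / |d⁽⁰⁾|²,   v(n) = R(n) − R_A,   d⁽⁰⁾ = R_B − R_A,

so the end states sit at x = 0 and x = 1 exactly.

Cross-correlation maps come in two flavours, selected explicitly by the
caller because they answer different questions: the *path deformation* map
uses the displacement between consecutive path conformers (what actually
moved, at that moment of the transition), while the *ANM mode* map uses a
low-frequency eigenvector of one end state's network (what the topology of
that state prefers to move).  Entries are cosines in [−1, 1]; residues with
(near-)zero displacement have no defined direction and are reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .elastic_network import AnmModel, compute_modes
from .errors import DegenerateLineError, IntegrityError, MappingError, TanmError
from .structure_io import CaStructure, ResidueMapping, parse_residue_spec
from .transition_path import Conformer, TransitionPath, kabsch
from .two_state_potential import two_state_energy

__all__ = [
    "CrossCorrelationMap",
    "PGP_DEFAULT_PAIRS",
    "PGP_DEFAULT_LINES",
    "reaction_coordinate",
    "energy_profile",
    "pair_distances",
    "segment_angle",
    "rmsd_series",
    "closest_conformer",
    "cross_correlation",
    "path_deformation_map",
    "anm_mode_map",
]

#: Residue pairs tracking the P-gp transition (chain A author numbering):
#: extracellular loops ASP87–ASP743, TRP212–TRP855, GLY324–LEU968; the
#: drug-binding middle MET68–PHE728 and ASP188–SER831; the intracellular
#: helices TRP162–TRP803 and ILE265–VAL908; and the nucleotide-binding
#: domains GLY430–GLY1178, GLY533–GLY1073, GLU556–GLU1201.
PGP_DEFAULT_PAIRS: list[tuple[str, str]] = [
    ("A:87", "A:743"),
    ("A:212", "A:855"),
    ("A:324", "A:968"),
    ("A:68", "A:728"),
    ("A:188", "A:831"),
    ("A:162", "A:803"),
    ("A:265", "A:908"),
    ("A:430", "A:1178"),
    ("A:533", "A:1073"),
    ("A:556", "A:1201"),
]

#: Line segments through the two nucleotide-binding domains (L413–K536 and
#: E1059–K1181) whose mutual acute angle monitors the inter-domain twist.
PGP_DEFAULT_LINES: tuple[tuple[str, str], tuple[str, str]] = (
    ("A:413", "A:536"),
    ("A:1059", "A:1181"),
)

_ZERO_DISPLACEMENT = 1e-12


@dataclass(frozen=True)
class CrossCorrelationMap:
    """Symmetric N×N cosine-correlation matrix of residue displacements."""

    matrix: np.ndarray
    source: str  # "PATH_DEFORMATION" or "ANM_MODE"
    conformer_or_mode_index: int


def _conformer_list(path) -> list[Conformer]:
    return list(getattr(path, "conformers", path))


def reaction_coordinate(
    path,
    coords_a: np.ndarray | None = None,
    coords_b: np.ndarray | None = None,
) -> np.ndarray:
    """Scalar progress variable per conformer, 0 at end A and 1 at end B.

    End-state coordinates default to the path's stored (superposed) ends; for
    a bare conformer list they must be supplied (or default to the first and
    last conformers).
    """
    conformers = _conformer_list(path)
    if coords_a is None:
        coords_a = getattr(path, "coords_a", None)
        if coords_a is None:
            coords_a = conformers[0].coords
    if coords_b is None:
        coords_b = getattr(path, "coords_b", None)
        if coords_b is None:
            coords_b = conformers[-1].coords
    d0 = (np.asarray(coords_b, float) - np.asarray(coords_a, float)).ravel()
    denom = float(d0 @ d0)
    if denom == 0.0:
        return np.zeros(len(conformers))
    return np.array(
        [((c.coords - coords_a).ravel() @ d0) / denom for c in conformers]
    )


def energy_profile(path, potential=None) -> pd.DataFrame:
    """Per-conformer energies, re-evaluated from coordinates.

    Columns: ``index`` (1-based), ``branch``, ``x``, ``u_a``, ``u_b``, ``u``.
    Cached conformer energies are cross-checked against re-evaluation; a
    disagreement beyond 1e-9 kcal/mol is an integrity failure.
    """
    conformers = _conformer_list(path)
    if potential is None:
        potential = getattr(path, "potential", None)
        if potential is None:
            raise TanmError("no potential available to re-evaluate energies")
    x = reaction_coordinate(path)
    rows = []
    for k, c in enumerate(conformers):
        e = two_state_energy(potential, c.coords)
        for cached, fresh, name in (
            (c.energies.u_a, e.u_a, "u_a"),
            (c.energies.u_b, e.u_b, "u_b"),
            (c.energies.u, e.u, "u"),
        ):
            if abs(cached - fresh) > 1e-9:
                raise IntegrityError(
                    f"conformer {k}: cached {name}={cached!r} vs re-evaluated {fresh!r}"
                )
        rows.append(
            {
                "index": k + 1,
                "branch": c.branch,
                "x": x[k],
                "u_a": e.u_a,
                "u_b": e.u_b,
                "u": e.u,
            }
        )
    return pd.DataFrame(rows, columns=["index", "branch", "x", "u_a", "u_b", "u"])


def _resolve_residue(path, spec) -> tuple[int, str]:
    """Map a residue spec to a row index in the path's working set."""
    residues = getattr(path, "residues", None)
    if residues is None:
        raise MappingError("path carries no residue identifiers")
    key = parse_residue_spec(spec) if isinstance(spec, str) else tuple(spec)
    for i, r in enumerate(residues):
        if r.key == key:
            return i, f"{r.name}{r.number}"
    raise MappingError(f"residue {spec!r} not in the path's residue set")


def pair_distances(path, pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Cα–Cα distances (Å) per conformer for each residue pair.

    Columns: ``index`` (1-based) followed by one ``NAME<num>-NAME<num>``
    column per pair, in input order.
    """
    conformers = _conformer_list(path)
    resolved = []
    for spec_i, spec_j in pairs:
        (i, name_i) = _resolve_residue(path, spec_i)
        (j, name_j) = _resolve_residue(path, spec_j)
        resolved.append((i, j, f"{name_i}-{name_j}"))
    data = {"index": np.arange(1, len(conformers) + 1)}
    coords = np.stack([c.coords for c in conformers])
    for i, j, label in resolved:
        data[label] = np.linalg.norm(coords[:, i] - coords[:, j], axis=1)
    return pd.DataFrame(data)


def segment_angle(
    path,
    line1: tuple[str, str],
    line2: tuple[str, str],
) -> np.ndarray:
    """Acute angle (degrees) between two residue-defined lines, per conformer.

    Lines are undirected, so the angle is arccos(|û₁·û₂|) ∈ [0°, 90°]:
    parallel and antiparallel both read 0°.
    """
    conformers = _conformer_list(path)
    (i1, _), (j1, _) = _resolve_residue(path, line1[0]), _resolve_residue(path, line1[1])
    (i2, _), (j2, _) = _resolve_residue(path, line2[0]), _resolve_residue(path, line2[1])
    angles = np.empty(len(conformers))
    for k, c in enumerate(conformers):
        v1 = c.coords[j1] - c.coords[i1]
        v2 = c.coords[j2] - c.coords[i2]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 <= 1e-6 or n2 <= 1e-6:
            raise DegenerateLineError(
                f"conformer {k}: line of length {min(n1, n2):.2e} Å"
            )
        cosine = abs(float(v1 @ v2) / (n1 * n2))
        angles[k] = np.degrees(np.arccos(min(cosine, 1.0)))
    return angles


def rmsd_series(
    path,
    reference: CaStructure,
    mapping: ResidueMapping | None = None,
) -> np.ndarray:
    """Kabsch-minimized RMSD of every conformer to a reference structure.

    ``mapping`` pairs the path's residue rows (first column) with reference
    rows (second column); by default residues with identical identifiers are
    matched.  At least 3 residues must map.
    """
    conformers = _conformer_list(path)
    residues = getattr(path, "residues", None)
    if mapping is None:
        if residues is None:
            raise MappingError("path carries no residue identifiers")
        ref_index = {r.key: i for i, r in enumerate(reference.residues)}
        pairs = [
            (i, ref_index[r.key]) for i, r in enumerate(residues) if r.key in ref_index
        ]
        if not pairs:
            raise MappingError("reference shares no residues with the path")
        mapping = ResidueMapping(np.array(pairs, dtype=int))
    if mapping.n_common < 3:
        raise MappingError("need at least 3 mapped residues for RMSD")
    ref_xyz = reference.coords[mapping.b_indices]
    out = np.empty(len(conformers))
    for k, c in enumerate(conformers):
        _, _, out[k] = kabsch(c.coords[mapping.a_indices], ref_xyz)
    return out


def closest_conformer(
    path,
    reference: CaStructure,
    mapping: ResidueMapping | None = None,
) -> tuple[int, float]:
    """(0-based index, RMSD) of the conformer closest to the reference."""
    series = rmsd_series(path, reference, mapping)
    k = int(np.argmin(series))
    return k, float(series[k])


def cross_correlation(displacement: np.ndarray) -> np.ndarray:
    """Cosine cross-correlation matrix of a per-residue 3-vector field.

    Entry (i, j) is the cosine of the angle between the displacement vectors
    of residues i and j; the matrix is symmetric with unit diagonal for
    moving residues, and rows/columns of residues whose displacement norm is
    below 1e-12 are NaN (the direction is undefined).
    """
    v = np.asarray(displacement, float)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError("displacement must be n×3")
    norms = np.linalg.norm(v, axis=1)
    moving = norms > _ZERO_DISPLACEMENT
    if not moving.any():
        raise TanmError("all residue displacements are zero")
    unit = np.zeros_like(v)
    unit[moving] = v[moving] / norms[moving, None]
    c = np.clip(unit @ unit.T, -1.0, 1.0)
    c[~moving, :] = np.nan
    c[:, ~moving] = np.nan
    idx = np.nonzero(moving)[0]
    c[idx, idx] = 1.0
    return c


def path_deformation_map(path, k: int) -> CrossCorrelationMap:
    """Cross-correlation of the deformation between conformers k and k+1."""
    conformers = _conformer_list(path)
    if not (0 <= k < len(conformers) - 1):
        raise IndexError(f"k must be in [0, {len(conformers) - 2}]")
    v = conformers[k + 1].coords - conformers[k].coords
    return CrossCorrelationMap(
        matrix=cross_correlation(v),
        source="PATH_DEFORMATION",
        conformer_or_mode_index=k,
    )


def anm_mode_map(model: AnmModel, mode_index: int = 0) -> CrossCorrelationMap:
    """Cross-correlation of a low-frequency ANM eigenvector of one end state."""
    modes = compute_modes(model, n_modes=mode_index + 1)
    if mode_index >= modes.eigenvectors.shape[1]:
        raise IndexError(f"mode {mode_index} not available")
    v = modes.eigenvectors[:, mode_index].reshape(-1, 3)
    return CrossCorrelationMap(
        matrix=cross_correlation(v),
        source="ANM_MODE",
        conformer_or_mode_index=mode_index,
    )
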