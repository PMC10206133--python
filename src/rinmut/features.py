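"""Per-residue structural and evolutionary features.

Two attributes drive the mutation classifiers: relative surface exposure
(solvent-accessible surface area divided by the residue type's maximum
area in an extended Gly-X-Gly reference tripeptide) and evolutionary
conservation (either imported from a precomputed table, or computed from a
multiple sequence alignment as one minus the normalized Shannon entropy of
each column).  Conservation is always oriented so that HIGHER means MORE
conserved; imported tables in the opposite convention are flipped on load.

The SASA computation is a deterministic Shrake--Rupley: each atom's sphere
(van der Waals radius + probe radius) is sampled on a golden-spiral point
lattice, and the accessible area is the fraction of points not buried in
any neighboring atom's expanded sphere.  No random numbers are involved,
so results are bit-reproducible for a fixed point count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .rin import ResidueNetwork
from .structure_io import NodeIndexMap, StructureModel

__all__ = [
    "VDW_RADII",
    "golden_spiral_points",
    "compute_sasa",
    "load_reference_areas",
    "relative_exposure",
    "conservation_from_msa",
    "load_conservation",
    "FeatureTable",
    "assemble_features",
]

#: Van der Waals radii (angstrom) for elements common in protein structures.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.20,
    "D": 1.20,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def golden_spiral_points(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (deterministic lattice)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(
    s: StructureModel,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
    include_hydrogens: bool = False,
) -> np.ndarray:
    """Shrake--Rupley solvent-accessible surface area per residue (angstrom^2).

    Per-atom area = 4*pi*(r+p)^2 * (fraction of lattice points outside all
    other atoms' expanded spheres); per-residue area sums its atoms, so the
    structure total equals the sum over residues by construction.
    """
    coords = []
    radii = []
    res_index = []
    for ri, res in enumerate(s.residues):
        atoms = res.atoms if include_hydrogens else res.heavy_atoms()
        for a in atoms:
            el = a.element.upper()
            if el not in VDW_RADII:
                raise ValueError(
                    f"no van der Waals radius for element {a.element!r} "
                    f"(atom {a.name} in residue {res.legacy_position})"
                )
            coords.append(a.xyz)
            radii.append(VDW_RADII[el])
            res_index.append(ri)
    xyz = np.asarray(coords)
    radii = np.asarray(radii) + probe_radius
    res_index = np.asarray(res_index)
    n_atoms = len(radii)

    unit = golden_spiral_points(sphere_points)
    tree = cKDTree(xyz)
    max_reach = 2.0 * radii.max()
    per_atom = np.zeros(n_atoms)
    for i in range(n_atoms):
        pts = xyz[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(xyz[i], max_reach) if j != i]
        accessible = np.ones(sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        per_atom[i] = 4.0 * math.pi * radii[i] ** 2 * accessible.mean()

    out = np.zeros(s.n_residues)
    np.add.at(out, res_index, per_atom)
    return out


def load_reference_areas(path: str | Path | None = None) -> dict[str, float]:
    """Maximum accessible areas (Gly-X-Gly reference) per 3-letter residue code.

    Defaults to the packaged table; a user table with columns
    (residue, max_asa) overrides it.
    """
    if path is None:
        src = resources.files("rinmut").joinpath("data/max_asa_gxg.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    ref: dict[str, float] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        res, area = line.split()
        ref[res.upper()] = float(area)
        if float(area) <= 0:
            raise ValueError(f"non-positive reference area for {res}")
    missing = {r for r in _STANDARD_RESIDUES} - set(ref)
    if missing:
        raise ValueError(f"reference table missing residues: {sorted(missing)}")
    return ref


_STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL"
).split()


def relative_exposure(
    areas: np.ndarray,
    residue_names: Sequence[str],
    ref: Mapping[str, float] | None = None,
    flag_threshold: float = 1.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue area / reference-state area of the same residue type.

    Ratios are not clipped (slightly above 1 is possible at chain termini);
    values above `flag_threshold` are flagged for inspection.
    """
    if ref is None:
        ref = load_reference_areas()
    ratios = np.empty(len(areas))
    for i, (area, name) in enumerate(zip(areas, residue_names)):
        key = name.upper()
        if key not in ref:
            raise ValueError(f"residue type {name!r} missing from reference table")
        ratios[i] = area / ref[key]
    return ratios, ratios > flag_threshold


def _read_fasta_alignment(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def conservation_from_msa(
    msa: str | Path | Sequence[tuple[str, str]] | Sequence[str],
    focus_row: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Conservation per ungapped focus-row position from an alignment.

    Column score = 1 - H/ln(20), with H the Shannon entropy of the amino
    acid distribution in the column (gaps excluded from the counts), so an
    invariant column scores 1 and a uniform column scores 0.  Columns
    containing only gaps are imputed with the mean of scored columns and
    flagged.  Returns (scores, imputed_flags) over the focus row's
    ungapped positions.
    """
    if isinstance(msa, (str, Path)):
        rows = _read_fasta_alignment(msa)
    else:
        rows = [(f"seq{i}", r) if isinstance(r, str) else r for i, r in enumerate(msa)]
    if not rows:
        raise ValueError("empty alignment")
    if not 0 <= focus_row < len(rows):
        raise ValueError(f"focus row {focus_row} out of range (n={len(rows)})")
    seqs = [seq for _, seq in rows]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("alignment rows have unequal lengths")

    focus = seqs[focus_row]
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    col_scores = np.full(length, np.nan)
    for c in range(length):
        counts = np.zeros(20)
        for s in seqs:
            i = aa_index.get(s[c])
            if i is not None:
                counts[i] += 1
        total = counts.sum()
        if total == 0:
            continue  # all-gap column, impute later
        p = counts[counts > 0] / total
        h = -np.sum(p * np.log(p))
        col_scores[c] = 1.0 - h / math.log(20.0)

    keep = [c for c in range(length) if focus[c] not in ("-", ".")]
    scores = col_scores[keep]
    imputed = np.isnan(scores)
    if imputed.any():
        fill = np.nanmean(scores) if not imputed.all() else 0.0
        scores = np.where(imputed, fill, scores)
    return scores, imputed


def load_conservation(
    path: str | Path,
    m: NodeIndexMap,
    orientation: str = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Load a (legacy_position, score) TSV and map scores onto node ids.

    Orientation handling standardizes to higher = more conserved:

    - ``auto``: integer grades confined to 1..9 are treated as the common
      9-step grade scale with 9 most conserved and mapped to [0, 1];
      continuous scores are assumed to follow the normalized-rate
      convention (lower = more conserved), so they are flipped then
      min--max scaled.
    - ``higher_conserved`` / ``lower_conserved``: force the input
      convention; scores are min--max scaled (after flipping for
      ``lower_conserved``).

    Nodes absent from the table are imputed with the mean and flagged.
    Returns (scores_per_node, imputed_flags).
    """
    raw: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("legacy"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                raw[int(parts[0])] = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc

    values = np.array(list(raw.values()))
    if orientation not in ("auto", "higher_conserved", "lower_conserved"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "auto":
        is_grades = np.all(values == np.round(values)) and values.min() >= 1 and values.max() <= 9
        orientation = "higher_conserved" if is_grades else "lower_conserved"
        if is_grades:
            raw = {k: (v - 1.0) / 8.0 for k, v in raw.items()}
            orientation = "already_scaled"

    if orientation != "already_scaled":
        lo, hi = values.min(), values.max()
        span = hi - lo if hi > lo else 1.0
        if orientation == "higher_conserved":
            raw = {k: (v - lo) / span for k, v in raw.items()}
        else:
            raw = {k: (hi - v) / span for k, v in raw.items()}

    n = len(m)
    out = np.full(n, np.nan)
    for pos, score in raw.items():
        nid = m.get(pos)
        if nid is not None:
            out[nid] = score
    imputed = np.isnan(out)
    if imputed.any():
        fill = np.nanmean(out) if not imputed.all() else 0.0
        out = np.where(imputed, fill, out)
    return out, imputed


@dataclass
class FeatureTable:
    """Per-node attribute matrix with scaling metadata.

    `raw` holds unscaled values; :meth:`scaled` min--max maps each column
    to [0, 1], either from its own statistics or from supplied (train-split)
    statistics.  A column with zero range maps to 0.5 everywhere.
    """

    names: list[str]
    raw: np.ndarray  # (n_nodes, n_features)
    imputed: np.ndarray  # (n_nodes,) bool

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[1] != len(self.names):
            raise ValueError("feature matrix shape inconsistent with names")

    @property
    def n_nodes(self) -> int:
        return self.raw.shape[0]

    def scaled(
        self, stats: Optional[tuple[np.ndarray, np.ndarray]] = None
    ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
        """(scaled_matrix, (mins, maxs)); stats from self when not supplied."""
        if stats is None:
            mins = self.raw.min(axis=0)
            maxs = self.raw.max(axis=0)
        else:
            mins, maxs = stats
        span = maxs - mins
        out = np.empty_like(self.raw)
        for j in range(self.raw.shape[1]):
            if span[j] > 0:
                out[:, j] = (self.raw[:, j] - mins[j]) / span[j]
            else:
                out[:, j] = 0.5
        return out, (mins, maxs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\t" + "\t".join(self.names) + "\timputed\n")
            for i in range(self.n_nodes):
                row = "\t".join(f"{v:.6g}" for v in self.raw[i])
                fh.write(f"{i}\t{row}\t{int(self.imputed[i])}\n")


def assemble_features(
    net: ResidueNetwork,
    exposure: np.ndarray,
    conservation: np.ndarray,
    extras: Sequence[str] = (),
    exposure_imputed: Optional[np.ndarray] = None,
    conservation_imputed: Optional[np.ndarray] = None,
) -> FeatureTable:
    """Stack per-node attributes into a :class:`FeatureTable`.

    `extras` may request "degree" (node degree in the network).  Exposure
    and conservation must cover every network node (impute upstream).
    """
    n = net.n_nodes
    exposure = np.asarray(exposure, dtype=float)
    conservation = np.asarray(conservation, dtype=float)
    if len(exposure) != n or len(conservation) != n:
        raise ValueError(
            f"features must cover all {n} nodes "
            f"(got exposure {len(exposure)}, conservation {len(conservation)})"
        )
    if np.isnan(exposure).any() or np.isnan(conservation).any():
        raise ValueError("NaN feature encountered; impute before assembly")

    names = ["relative_exposure", "conservation"]
    cols = [exposure, conservation]
    for extra in extras:
        if extra == "degree":
            names.append("degree")
            cols.append(net.degree().astype(float))
        else:
            raise ValueError(f"unknown extra feature {extra!r}")

    imputed = np.zeros(n, dtype=bool)
    if exposure_imputed is not None:
        imputed |= np.asarray(exposure_imputed, dtype=bool)
    if conservation_imputed is not None:
        imputed |= np.asarray(conservation_imputed, dtype=bool)
    return FeatureTable(names=names, raw=np.column_stack(cols), imputed=imputed)
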