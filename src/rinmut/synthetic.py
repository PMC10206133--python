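"""Deterministic synthetic fixtures: toy structures, alignments and
mutation tables with the statistical structure the pipeline assumes.

The generators plant a recoverable signal: mutation labels follow a
burial-and-conservation rule (a substitution is deleterious when its
residue is more buried than the median and more conserved than the
median), corrupted by a configurable label-noise rate and subsampled to a
configurable class imbalance.  This mirrors the empirical pattern that
buried, conserved residues are intolerant to substitution, and gives every
stage of the pipeline - and the end-to-end classifier - a testable target
whose Bayes accuracy is known by construction.

Fixtures are written in standard formats (PDB, FASTA, CSV) so they double
as format-reader tests.  All randomness comes from one generator seeded by
the spec.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import (
    AMINO_ACIDS,
    FeatureTable,
    assemble_features,
    compute_sasa,
    conservation_from_msa,
    relative_exposure,
)
from .mutations import (
    LabeledDataset,
    attach_to_nodes,
    binarize_percent_data,
    binarize_severity,
    parse_mutation_table,
    sanitize,
)
from .rin import ResidueNetwork, find_contacts, normalize_weights, simplify
from .structure_io import (
    Atom,
    ExcisionPlan,
    NodeIndexMap,
    ONE_TO_THREE,
    Residue,
    StructureModel,
    excise_segments,
)

__all__ = [
    "FixtureSpec",
    "make_structure",
    "make_msa",
    "write_fasta",
    "write_pdb",
    "make_mutation_table",
    "Benchmark",
    "make_benchmark",
]


@dataclass(frozen=True)
class FixtureSpec:
    n_residues: int = 420
    fold_style: str = "compact-blob"  # extended | helix | compact-blob
    n_msa_rows: int = 40
    conserved_fraction: float = 0.45
    mutation_rate: float = 0.5  # per-row substitution rate in mutable columns
    label_rule: str = "burial_and_conservation"
    label_noise: float = 0.1
    class_imbalance_target: float = 0.66
    n_instances: int = 300
    n_malformed: int = 0
    label_kind: str = "phenotype"  # phenotype | percent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues")
        for frac in (
            self.conserved_fraction, self.label_noise,
            self.class_imbalance_target, self.mutation_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.fold_style not in ("extended", "helix", "compact-blob"):
            raise ValueError(f"unknown fold style {self.fold_style!r}")
        if self.label_rule != "burial_and_conservation":
            raise ValueError(f"unknown label rule {self.label_rule!r}")
        if self.label_kind not in ("phenotype", "percent"):
            raise ValueError(f"unknown label kind {self.label_kind!r}")


CA_CA = 3.8  # ideal consecutive alpha-carbon distance, angstrom


def _ca_trace(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_residues
    if spec.fold_style == "extended":
        return np.column_stack([CA_CA * np.arange(n), np.zeros(n), np.zeros(n)])
    if spec.fold_style == "helix":
        # ideal alpha helix: 2.3 A radius, 1.5 A rise, 100 degrees per residue
        t = np.deg2rad(100.0) * np.arange(n)
        return np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)])
    # compact blob: self-avoiding random walk confined to a sphere whose
    # volume allots ~110 A^3 per residue (globular-protein-like density)
    radius = (3.0 * n * 110.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    coords = np.zeros((n, 3))
    direction = _random_unit(rng)
    min_sep = 3.5
    for i in range(1, n):
        placed = False
        for attempt in range(300):
            sep = min_sep if attempt < 150 else 3.0
            rmax = radius if attempt < 200 else radius * 1.1
            proposal = direction * 0.5 + _random_unit(rng)
            proposal /= np.linalg.norm(proposal)
            cand = coords[i - 1] + CA_CA * proposal
            if np.linalg.norm(cand) > rmax:
                continue
            if i > 1:
                d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                if d.min() < sep:
                    continue
            coords[i] = cand
            direction = proposal
            placed = True
            break
        if not placed:  # give up on avoidance, keep chain connected
            coords[i] = coords[i - 1] + CA_CA * _random_unit(rng)
    return coords


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


#: Heavy side-chain atom counts of the standard residues (CB onwards).
SIDE_CHAIN_ATOMS = {
    "ALA": 1, "ARG": 7, "ASN": 4, "ASP": 4, "CYS": 2, "GLN": 5, "GLU": 5,
    "GLY": 0, "HIS": 6, "ILE": 4, "LEU": 4, "LYS": 5, "MET": 4, "PHE": 7,
    "PRO": 3, "SER": 2, "THR": 3, "TRP": 10, "TYR": 8, "VAL": 3,
}
_SC_NAMES = ["CB", "CG", "CD", "CE", "CZ", "CH", "CI", "CJ", "CK", "CL"]


def make_structure(spec: FixtureSpec) -> StructureModel:
    """Toy chain with backbone atoms (N/CA/C/O) on an idealized CA trace.

    Side chains carry the residue type's heavy-atom count as a short
    zig-zag chain pointing away from the backbone, so surface residues
    expose realistic areas relative to the packaged reference table.
    """
    rng = np.random.default_rng(spec.seed)
    ca = _ca_trace(spec, rng)
    seq = rng.choice(list(AMINO_ACIDS), size=spec.n_residues)
    residues = []
    n = spec.n_residues
    for i in range(n):
        nxt = ca[min(i + 1, n - 1)] - ca[max(i - 1, 0)]
        t = nxt / max(np.linalg.norm(nxt), 1e-9)
        helper = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(helper, t)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(t, helper)
        u /= np.linalg.norm(u)
        w = np.cross(t, u)
        if spec.fold_style == "compact-blob" and np.linalg.norm(ca[i]) > 1e-6:
            # side chains of surface residues point toward the solvent:
            # use the radial direction's component orthogonal to the chain
            radial = ca[i] / np.linalg.norm(ca[i])
            w_rad = radial - np.dot(radial, t) * t
            if np.linalg.norm(w_rad) > 0.3:
                w = w_rad / np.linalg.norm(w_rad)
        name3 = ONE_TO_THREE[seq[i]]
        atoms = [
            Atom("N", "N", tuple(ca[i] - 1.46 * _blend(t, u, -0.3))),
            Atom("CA", "C", tuple(ca[i])),
            Atom("C", "C", tuple(ca[i] + 1.52 * _blend(t, u, 0.3))),
            Atom("O", "O", tuple(ca[i] + 1.52 * _blend(t, u, 0.3) + 1.23 * u)),
        ]
        for j in range(SIDE_CHAIN_ATOMS[name3]):
            zig = 0.55 * u if j % 2 else -0.25 * u
            xyz = ca[i] + (1.53 + 1.35 * j) * w + (zig if j else 0.0 * u)
            atoms.append(Atom(_SC_NAMES[j], "C", tuple(xyz)))
        residues.append(Residue(legacy_position=i + 1, name=name3, atoms=atoms))
    return StructureModel(chain_id="A", residues=residues)


def _blend(t: np.ndarray, u: np.ndarray, mix: float) -> np.ndarray:
    v = t + mix * u
    return v / np.linalg.norm(v)


def write_pdb(s: StructureModel, path: str | Path) -> None:
    """Write the model as a minimal single-chain PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_atoms = sum(len(r.atoms) for r in s.residues)
    arr = struc.AtomArray(n_atoms)
    i = 0
    for res in s.residues:
        for a in res.atoms:
            arr.chain_id[i] = s.chain_id
            arr.res_id[i] = res.legacy_position
            arr.res_name[i] = res.name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
            arr.coord[i] = a.xyz
            i += 1
    arr.hetero[:] = False
    pdb_file = pdb.PDBFile()
    pdb.set_structure(pdb_file, arr)
    pdb_file.write(str(path))


def make_msa(
    sequence: str, spec: FixtureSpec, rng: Optional[np.random.Generator] = None
) -> list[tuple[str, str]]:
    """Alignment whose first (focus) row is `sequence`.

    A `conserved_fraction` of columns is invariant across rows; the other
    columns mutate per row at `mutation_rate`.  With a single row every
    column is trivially invariant.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    length = len(sequence)
    n_conserved = int(round(spec.conserved_fraction * length))
    conserved = set(rng.choice(length, size=n_conserved, replace=False).tolist())
    rows = [("focus", sequence)]
    aas = list(AMINO_ACIDS)
    for r in range(1, spec.n_msa_rows):
        chars = []
        for c, wt in enumerate(sequence):
            if c in conserved or rng.random() >= spec.mutation_rate:
                chars.append(wt)
            else:
                chars.append(aas[rng.integers(len(aas))])
        rows.append((f"homolog{r}", "".join(chars)))
    return rows


def write_fasta(msa: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in msa:
            fh.write(f">{name}\n{seq}\n")


def make_mutation_table(
    structure: StructureModel,
    features: FeatureTable,
    m: NodeIndexMap,
    spec: FixtureSpec,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Planted-label mutation table (CSV-ready DataFrame).

    Label = deleterious iff (exposure below its median AND conservation
    above its median), flipped with probability `label_noise`; classes are
    subsampled toward `class_imbalance_target` (majority = tolerated) and
    capped at `n_instances`.  `n_malformed` deliberately broken rows
    (multi-phenotype label, wild-type mismatch, stop codon) exercise the
    sanitation rules.
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    exposure = features.raw[:, features.names.index("relative_exposure")]
    conservation = features.raw[:, features.names.index("conservation")]
    exp_med = np.median(exposure)
    cons_med = np.median(conservation)
    seq_by_pos = structure.sequence_by_position()

    positions = []
    labels = []
    for pos, nid in sorted(m.pairs.items()):
        deleterious = exposure[nid] < exp_med and conservation[nid] > cons_med
        if rng.random() < spec.label_noise:
            deleterious = not deleterious
        positions.append(pos)
        labels.append(int(deleterious))
    positions = np.array(positions)
    labels = np.array(labels)

    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    r = spec.class_imbalance_target
    total = min(
        spec.n_instances,
        int(len(idx0) / r) if r > 0 else len(idx0),
        int(len(idx1) / (1.0 - r)) if r < 1 else len(idx1),
    )
    n0 = int(round(total * r))
    n1 = total - n0
    keep0 = rng.choice(idx0, size=n0, replace=False)
    keep1 = rng.choice(idx1, size=n1, replace=False)
    keep = np.sort(np.concatenate([keep0, keep1]))

    rows = []
    aas = list(AMINO_ACIDS)
    for i in keep:
        pos = int(positions[i])
        wt = seq_by_pos[pos]
        if spec.label_kind == "percent":
            mut = "A" if wt != "A" else "G"
            value = (
                float(rng.uniform(0.0, 45.0))
                if labels[i]
                else float(rng.uniform(55.0, 150.0))
            )
            rows.append({"position": pos, "wt": wt, "mut": mut, "percent": value})
        else:
            choices = [a for a in aas if a != wt]
            mut = choices[rng.integers(len(choices))]
            label = "Severe" if labels[i] else ("Mild", "Moderate")[rng.integers(2)]
            rows.append({"position": pos, "wt": wt, "mut": mut, "label": label})

    # deliberately malformed rows, cycling through the three defect kinds
    malformed_kinds = ["multi", "wt_mismatch", "stop"]
    for j in range(spec.n_malformed):
        kind = malformed_kinds[j % 3]
        pos = int(positions[rng.integers(len(positions))])
        wt = seq_by_pos[pos]
        bad_wt = next(a for a in aas if a != wt)
        row = {"position": pos, "wt": wt, "mut": "G" if wt != "G" else "A"}
        if spec.label_kind == "percent":
            row["percent"] = 50.0
            if kind == "multi":  # no multi-phenotype for percent tables
                kind = "wt_mismatch"
        else:
            row["label"] = "Mild"
        if kind == "multi":
            row["label"] = "Mild/Moderate"
        elif kind == "wt_mismatch":
            row["wt"] = bad_wt
        elif kind == "stop":
            row["mut"] = "*"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class Benchmark:
    """End-to-end fixture bundle produced by the real pipeline modules."""

    spec: FixtureSpec
    structure: StructureModel
    index_map: NodeIndexMap
    network: ResidueNetwork
    features: FeatureTable
    dataset: LabeledDataset
    msa: list[tuple[str, str]]
    mutation_table: pd.DataFrame


def make_benchmark(
    spec: FixtureSpec, out_dir: Optional[str | Path] = None
) -> Benchmark:
    """Generate inputs and push them through the actual pipeline stages.

    Structure -> contacts -> simplified, normalized network; SASA ->
    relative exposure; MSA -> conservation; planted mutation table ->
    parse -> sanitize -> binarize -> node-mapped labeled dataset.  When
    `out_dir` is given the intermediate files (PDB, FASTA, CSV) are kept
    there; otherwise the table round-trips through an in-memory buffer.
    """
    structure = make_structure(spec)
    _, index_map = excise_segments(structure, ExcisionPlan())

    edges = find_contacts(structure)
    net = normalize_weights(simplify(edges, n_nodes=structure.n_residues))

    areas = compute_sasa(structure)
    exposure, _ = relative_exposure(areas, [r.name for r in structure.residues])
    msa = make_msa(structure.sequence(), spec)
    conservation, cons_imputed = conservation_from_msa(msa, focus_row=0)
    features = assemble_features(
        net, exposure, conservation, conservation_imputed=cons_imputed
    )

    table = make_mutation_table(structure, features, index_map, spec)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_pdb(structure, out_dir / "structure.pdb")
        write_fasta(msa, out_dir / "alignment.fasta")
        table_path = out_dir / "mutations.csv"
        table.to_csv(table_path, index=False)
    else:
        import tempfile

        tmp = tempfile.NamedTemporaryFile(
            "w", suffix=".csv", delete=False
        )
        table.to_csv(tmp.name, index=False)
        table_path = Path(tmp.name)

    schema = (
        {"position": "position", "wt": "wt", "mut": "mut", "percent": "percent"}
        if spec.label_kind == "percent"
        else {"position": "position", "wt": "wt", "mut": "mut", "label": "label"}
    )
    records, parse_errors = parse_mutation_table(table_path, schema=schema)
    clean = sanitize(records, structure.sequence_by_position(), index_map)
    if spec.label_kind == "percent":
        binary = binarize_percent_data(clean)
        scheme = "activity"
    else:
        binary = binarize_severity(clean)
        scheme = "severity"
    dataset = attach_to_nodes(binary, index_map, features, label_scheme=scheme)
    dataset.drop_log = [(r, f"parse: {msg}") for r, msg in parse_errors] + list(
        dataset.drop_log
    )

    if out_dir is None:
        table_path.unlink(missing_ok=True)
    return Benchmark(
        spec=spec,
        structure=structure,
        index_map=index_map,
        network=net,
        features=features,
        dataset=dataset,
        msa=msa,
        mutation_table=table,
    )
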