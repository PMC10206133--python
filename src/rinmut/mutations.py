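"""Mutation-table ingestion, sanitation, labelling, and node mapping.

Clinical severity tables (mild/moderate/severe labels per substitution) and
in-vitro percent-of-wild-type tables (activity or antigen level per alanine
substitution) are parsed into records, cleaned by a fixed ordered rule set,
reduced to one instance per position by majority vote, binarized, and
attached to residue-network nodes.  Every dropped record is logged with the
first rule it violated, so input count = retained + sum of drop reasons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .features import AMINO_ACIDS, FeatureTable
from .structure_io import NodeIndexMap, THREE_TO_ONE

__all__ = [
    "MutationRecord",
    "LabeledDataset",
    "parse_mutation_table",
    "sanitize",
    "binarize_severity",
    "binarize_percent",
    "attach_to_nodes",
]

STOP_SYMBOLS = {"*", "TER", "X"}

_HGVS_PROTEIN = re.compile(
    r"^p\.\(?([A-Za-z]{3})(-?\d+)([A-Za-z]{3}|\*)\)?$"
)


def _to_one_letter(token: str) -> str:
    """1-letter residue code from 1- or 3-letter input; '*' for stop."""
    token = token.strip()
    if not token:
        raise ValueError("empty residue code")
    if token in STOP_SYMBOLS or token.upper() == "TER":
        return "*"
    if len(token) == 1:
        up = token.upper()
        if up in AMINO_ACIDS:
            return up
        raise ValueError(f"unknown residue code {token!r}")
    up = token.upper()
    if up in THREE_TO_ONE:
        return THREE_TO_ONE[up]
    raise ValueError(f"unknown residue code {token!r}")


@dataclass(frozen=True)
class MutationRecord:
    legacy_position: int
    wt_residue: str  # 1-letter
    mut_residue: str  # 1-letter, '*' for stop
    raw_label: Optional[str] = None  # e.g. "Mild", "Severe", "Mild/Moderate"
    percent_of_wt: Optional[float] = None


@dataclass
class LabeledDataset:
    """Binary-labeled instances mapped to network nodes.

    One instance per (post-vote) position; `positions` keeps the legacy
    coordinate for traceability.  `drop_log` lists (identifier, reason) for
    every record removed anywhere in the pipeline.
    """

    node_ids: np.ndarray
    labels: np.ndarray  # 0/1
    positions: np.ndarray
    label_scheme: str  # severity | activity | antigen
    augmentation: Optional[np.ndarray] = None  # (n, k) extra instance features
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.node_ids)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\tlabel\tlegacy_position\n")
            for nid, lab, pos in zip(self.node_ids, self.labels, self.positions):
                fh.write(f"{nid}\t{lab}\t{pos}\n")


def parse_mutation_table(
    path: str | Path,
    schema: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
) -> tuple[list[MutationRecord], list[tuple[str, str]]]:
    """Parse a delimited mutation table into records.

    `schema` maps logical fields to column names.  Two layouts are
    supported: explicit columns {"position", "wt", "mut"} or a single
    HGVS-protein column {"hgvs"} (e.g. "p.Arg2169His").  The label comes
    from schema key "label" (text phenotype) or "percent" (numeric
    percent-of-wild-type).  Rows with unparseable residues or positions are
    collected as (row, reason) errors and dropped, not raised.
    """
    schema = dict(schema or {})
    schema.setdefault("position", "position")
    schema.setdefault("wt", "wt")
    schema.setdefault("mut", "mut")
    df = pd.read_csv(path, sep=sep, engine="python")

    records: list[MutationRecord] = []
    errors: list[tuple[str, str]] = []
    for idx, row in df.iterrows():
        rid = f"row{idx}"
        try:
            if "hgvs" in schema:
                cell = str(row[schema["hgvs"]]).strip()
                m = _HGVS_PROTEIN.match(cell)
                if not m:
                    raise ValueError(f"unparseable protein change {cell!r}")
                wt = _to_one_letter(m.group(1))
                pos = int(m.group(2))
                mut = _to_one_letter(m.group(3))
            else:
                pos = int(row[schema["position"]])
                wt = _to_one_letter(str(row[schema["wt"]]))
                mut = _to_one_letter(str(row[schema["mut"]]))
            label = None
            percent = None
            if "label" in schema:
                label = str(row[schema["label"]]).strip()
            if "percent" in schema:
                percent = float(row[schema["percent"]])
                if percent < 0:
                    raise ValueError(f"negative percent-of-WT {percent}")
            records.append(
                MutationRecord(
                    legacy_position=pos,
                    wt_residue=wt,
                    mut_residue=mut,
                    raw_label=label,
                    percent_of_wt=percent,
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append((rid, str(exc)))
    return records, errors


@dataclass
class SanitizedData:
    """One entry per surviving position, plus the audited drop log."""

    positions: np.ndarray
    labels: list  # str phenotype or float percent, parallel to positions
    label_kind: str  # "phenotype" | "percent"
    drop_log: list[tuple[str, str]] = field(default_factory=list)
    n_input_records: int = 0
    n_voted_records: int = 0  # records entering the per-position vote


def sanitize(
    records: Sequence[MutationRecord],
    sequence_by_position: Mapping[int, str],
    m: NodeIndexMap,
) -> SanitizedData:
    """Apply the ordered drop rules, then per-position majority vote.

    Rules, in order (a record violating several is logged under the first):

    1. multi-phenotype label (e.g. "Mild/Moderate");
    2. wild-type residue mismatch against the retained sequence;
    3. stop-codon substitution;
    4. position excised from (or absent in) the network.

    Phenotype records at the same position are then reduced by majority
    vote; tied positions are dropped (only unambiguous cases are kept).
    Percent-valued records at a duplicated position are averaged.
    """
    kept: list[MutationRecord] = []
    log: list[tuple[str, str]] = []
    for i, rec in enumerate(records):
        rid = f"{rec.wt_residue}{rec.legacy_position}{rec.mut_residue}"
        if rec.raw_label is not None and "/" in rec.raw_label:
            log.append((rid, "multi-phenotype label"))
            continue
        seq_res = sequence_by_position.get(rec.legacy_position)
        if seq_res is not None and rec.wt_residue != seq_res:
            log.append((rid, "wild-type mismatch"))
            continue
        if rec.mut_residue == "*":
            log.append((rid, "stop codon"))
            continue
        if m.get(rec.legacy_position) is None:
            log.append((rid, "position not in network"))
            continue
        kept.append(rec)

    label_kind = "percent" if kept and kept[0].percent_of_wt is not None else "phenotype"
    by_pos: dict[int, list[MutationRecord]] = {}
    for rec in kept:
        by_pos.setdefault(rec.legacy_position, []).append(rec)

    positions: list[int] = []
    labels: list = []
    for pos in sorted(by_pos):
        group = by_pos[pos]
        if label_kind == "percent":
            positions.append(pos)
            labels.append(float(np.mean([r.percent_of_wt for r in group])))
            continue
        counts: dict[str, int] = {}
        for r in group:
            counts[r.raw_label] = counts.get(r.raw_label, 0) + 1
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        if len(winners) > 1:
            log.append((f"pos{pos}", "tied majority vote"))
            continue
        positions.append(pos)
        labels.append(winners[0])

    return SanitizedData(
        positions=np.array(positions, dtype=int),
        labels=labels,
        label_kind=label_kind,
        drop_log=log,
        n_input_records=len(records),
        n_voted_records=len(kept),
    )


SEVERITY_CLASSES = {"MILD": 0, "MODERATE": 0, "SEVERE": 1}


def binarize_severity(data: SanitizedData) -> SanitizedData:
    """Mild and moderate collapse to class 0; severe is class 1.

    Severe is the positive class: it is the clinically salient minority.
    """
    if data.label_kind != "phenotype":
        raise ValueError("binarize_severity expects phenotype labels")
    out_labels = []
    for lab in data.labels:
        key = str(lab).strip().upper()
        if key not in SEVERITY_CLASSES:
            raise ValueError(f"unknown severity label {lab!r}")
        out_labels.append(SEVERITY_CLASSES[key])
    return SanitizedData(
        positions=data.positions.copy(),
        labels=out_labels,
        label_kind="binary",
        drop_log=list(data.drop_log),
        n_input_records=data.n_input_records,
        n_voted_records=data.n_voted_records,
    )


def binarize_percent(values: Sequence[float], threshold: float = 50.0) -> np.ndarray:
    """Percent-of-wild-type -> binary class (1 = function disrupted).

    Values above the threshold are "retained" (0), below are "disrupted"
    (1).  A value exactly at the threshold is assigned to the retained
    class by convention (the strict inequalities of the assay definition
    leave it open).
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("percent-of-WT values must be non-negative")
    return (values < threshold).astype(int)


def binarize_percent_data(data: SanitizedData, threshold: float = 50.0) -> SanitizedData:
    """Apply :func:`binarize_percent` to a sanitized percent-valued dataset."""
    if data.label_kind != "percent":
        raise ValueError("binarize_percent_data expects percent labels")
    labels = binarize_percent(data.labels, threshold=threshold)
    return SanitizedData(
        positions=data.positions.copy(),
        labels=[int(v) for v in labels],
        label_kind="binary",
        drop_log=list(data.drop_log),
        n_input_records=data.n_input_records,
        n_voted_records=data.n_voted_records,
    )


def attach_to_nodes(
    data: SanitizedData,
    m: NodeIndexMap,
    features: Optional[FeatureTable] = None,
    label_scheme: str = "severity",
    augment_substitution: bool = False,
    mut_residues: Optional[Mapping[int, str]] = None,
) -> LabeledDataset:
    """Map sanitized binary-labeled positions onto network node ids.

    With `augment_substitution`, a 20-dim one-hot of the substituted
    residue (looked up per position in `mut_residues`) is attached per
    instance; it widens the classifier's readout, not the node features.
    """
    if data.label_kind != "binary":
        raise ValueError("attach_to_nodes expects binarized labels")
    node_ids = []
    labels = []
    positions = []
    log = list(data.drop_log)
    for pos, lab in zip(data.positions, data.labels):
        nid = m.get(int(pos))
        if nid is None:  # unreachable after sanitize rule 4; belt and braces
            log.append((f"pos{pos}", "position not in network"))
            continue
        node_ids.append(nid)
        labels.append(int(lab))
        positions.append(int(pos))
    node_arr = np.array(node_ids, dtype=int)
    if len(np.unique(node_arr)) != len(node_arr):
        raise AssertionError("duplicate node after majority vote")

    aug = None
    if augment_substitution:
        aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
        aug = np.zeros((len(node_arr), len(AMINO_ACIDS)))
        for row, pos in enumerate(positions):
            mut = (mut_residues or {}).get(pos)
            if mut in aa_index:
                aug[row, aa_index[mut]] = 1.0

    if features is not None and len(node_arr) and node_arr.max() >= features.n_nodes:
        raise ValueError("node id outside feature table")

    return LabeledDataset(
        node_ids=node_arr,
        labels=np.array(labels, dtype=int),
        positions=np.array(positions, dtype=int),
        label_scheme=label_scheme,
        augmentation=aug,
        drop_log=log,
    )
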