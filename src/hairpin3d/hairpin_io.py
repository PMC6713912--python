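"""Read and write the toolkit's on-disk artifacts.

Formats handled here:

* FASTA (multi-record, multiline) for hairpin candidates, via Biopython.
* Vienna dot-bracket triplets (header / sequence / structure, with the
  RNAfold-style parenthesized energy suffix) for secondary structures.
* Tab-separated feature tables carrying the fixed 36-column descriptor.
* Tab-separated per-repetition metric tables.
* Persisted trained models (joblib payload with a format-version tag).

Sequences are normalized to the RNA alphabet {A, C, G, U}: case is folded
to upper and T is mapped to U (miRBase-style inputs may use the DNA
alphabet). Ambiguity codes (N, R, Y, ...) are rejected under both alphabet
policies because the structural descriptor is undefined for unknown bases;
``strict`` and ``coerce`` differ in intent only (fail-loudly pipelines vs.
permissive ones) and currently validate the same legal set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlphabetError,
    InputError,
    ModelVersionError,
    SchemaError,
    StructureError,
)

LEGAL_INPUT = set("ACGUTacgut")
LABELS = ("positive", "negative", "unlabeled")

MODEL_FORMAT_VERSION = 1
CLASSIFIER_KINDS = ("decision_tree", "naive_bayes", "random_forest")


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence (one hairpin candidate).

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` the remainder (possibly empty); ``sequence`` is the
    normalized RNA string over {A, C, G, U}.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise InputError(f"record id must be a non-empty token, got {self.id!r}")
        if len(self.sequence) < 1:
            raise InputError(f"record {self.id!r} has an empty sequence")
        for i, c in enumerate(self.sequence):
            if c not in "ACGU":
                raise AlphabetError(self.id, i + 1, c)


@dataclass(frozen=True)
class StructuredRecord:
    """A sequence together with one dot-bracket secondary structure.

    ``score`` is the folding score: free energy in kcal/mol from an
    external thermodynamic folder (``score_kind='energy'``) or the number
    of base pairs from the built-in maximum-pairing folder
    (``score_kind='pair_count'``).
    """

    record: SequenceRecord
    structure: str
    score: float = 0.0
    score_kind: str = "unspecified"

    def __post_init__(self):
        if len(self.structure) != len(self.record.sequence):
            raise StructureError(
                f"record {self.record.id!r}: structure length "
                f"{len(self.structure)} != sequence length {len(self.record.sequence)}"
            )
        validate_dot_bracket(self.structure, self.record.id)
        if self.score_kind not in ("energy", "pair_count", "unspecified"):
            raise InputError(f"unknown score_kind {self.score_kind!r}")


def validate_dot_bracket(structure: str, record_id: str = "?") -> list:
    """Check balance and alphabet of a dot-bracket string; return pair list.

    Single-type brackets cannot cross, so balance is the only topological
    check needed (no pseudoknots are representable).
    """
    stack = []
    pairs = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(
                    f"record {record_id!r}: unbalanced ')' at position {i + 1}"
                )
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise StructureError(
                f"record {record_id!r}: illegal structure character {c!r} "
                f"at position {i + 1}"
            )
    if stack:
        raise StructureError(
            f"record {record_id!r}: unbalanced '(' at position {stack[-1] + 1}"
        )
    return pairs


def normalize_sequence(raw: str, record_id: str, policy: str = "coerce") -> str:
    if policy not in ("strict", "coerce"):
        raise ValueError(f"unknown alphabet policy {policy!r}")
    out = []
    for i, c in enumerate(raw):
        if c not in LEGAL_INPUT:
            raise AlphabetError(record_id, i + 1, c)
        u = c.upper()
        out.append("U" if u == "T" else u)
    return "".join(out)


def read_fasta(path, alphabet_policy: str = "coerce") -> list:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Multiline sequences are concatenated; headers split into id and
    description at the first whitespace. Raises :class:`InputError` for a
    missing or empty file and :class:`AlphabetError` (naming the record and
    1-based offset) for any character outside {A,C,G,U,T} in either case.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            if not seq:
                raise InputError(f"record {rec.id!r} has an empty sequence")
            description = rec.description[len(rec.id):].strip()
            records.append(
                SequenceRecord(
                    id=rec.id,
                    sequence=normalize_sequence(seq, rec.id, alphabet_policy),
                    description=description,
                )
            )
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    """Write records as FASTA; an empty iterable yields a valid empty file."""
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            out.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


_SCORE_RE = re.compile(r"^([.()]+)(?:\s+\(\s*(-?\d+(?:\.\d+)?)\s*\))?\s*$")


def read_vienna(path) -> list:
    """Read Vienna triplets (header / sequence / structure [+ score]).

    A trailing parenthesized number on the structure line, as emitted by
    RNAfold (e.g. ``(((...))) (-7.20)``), is parsed as a folding energy.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"Vienna file not found: {path}")
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    if not lines:
        raise InputError(f"empty Vienna file: {path}")
    out = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise InputError(
                f"{path}: expected FASTA header at line {i + 1}, got {lines[i]!r}"
            )
        header = lines[i][1:].strip()
        rid, _, desc = header.partition(" ")
        if i + 2 >= len(lines):
            raise InputError(f"{path}: truncated record {rid!r}")
        seq = normalize_sequence(lines[i + 1].strip(), rid)
        m = _SCORE_RE.match(lines[i + 2].strip())
        if m is None:
            raise InputError(
                f"{path}: malformed structure line for record {rid!r}: "
                f"{lines[i + 2]!r}"
            )
        structure, score_str = m.group(1), m.group(2)
        record = SequenceRecord(id=rid, sequence=seq, description=desc.strip())
        if score_str is not None:
            sr = StructuredRecord(record, structure, float(score_str), "energy")
        else:
            sr = StructuredRecord(record, structure)
        out.append(sr)
        i += 3
    return out


def write_vienna(structured: Iterable[StructuredRecord], path) -> None:
    """Write Vienna triplets; only energy scores get a parenthesized suffix."""
    with open(path, "w") as out:
        for sr in structured:
            header = f">{sr.record.id}"
            if sr.record.description:
                header += f" {sr.record.description}"
            out.write(header + "\n")
            out.write(sr.record.sequence + "\n")
            if sr.score_kind == "energy":
                out.write(f"{sr.structure} ({sr.score:.2f})\n")
            else:
                out.write(sr.structure + "\n")


@dataclass
class FeatureTable:
    """Rows of the fixed 36-component descriptor, aligned to record ids."""

    ids: list
    matrix: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        from .graph3d import FEATURE_COLUMNS  # local import: avoid cycle

        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(FEATURE_COLUMNS):
            raise SchemaError(
                f"feature matrix must have {len(FEATURE_COLUMNS)} columns, "
                f"got shape {self.matrix.shape}"
            )
        if len(self.ids) != self.matrix.shape[0]:
            raise SchemaError("ids and matrix row count differ")
        if not self.labels:
            self.labels = ["unlabeled"] * len(self.ids)
        if len(self.labels) != len(self.ids):
            raise SchemaError("labels and ids length differ")
        for lab in self.labels:
            if lab not in LABELS:
                raise SchemaError(f"unknown label {lab!r}")

    @property
    def column_names(self) -> tuple:
        from .graph3d import FEATURE_COLUMNS

        return FEATURE_COLUMNS

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            ids=[self.ids[i] for i in idx],
            matrix=self.matrix[idx],
            labels=[self.labels[i] for i in idx],
        )

    def with_labels(self, label: str) -> "FeatureTable":
        return FeatureTable(self.ids, self.matrix, [label] * len(self.ids))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.column_names))
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.ids)
        return df


def concat_tables(tables: Sequence[FeatureTable]) -> FeatureTable:
    return FeatureTable(
        ids=[i for t in tables for i in t.ids],
        matrix=np.vstack([t.matrix for t in tables]),
        labels=[l for t in tables for l in t.labels],
    )


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a TSV with the fixed header (id, label, 36 descriptor names).

    Values are printed with 17 significant digits so the round trip is
    lossless well past 12 significant digits.
    """
    with open(path, "w") as out:
        out.write("id\tlabel\t" + "\t".join(table.column_names) + "\n")
        for rid, lab, row in zip(table.ids, table.labels, table.matrix):
            cells = "\t".join(f"{v:.17g}" for v in row)
            out.write(f"{rid}\t{lab}\t{cells}\n")


def read_feature_table(path) -> FeatureTable:
    from .graph3d import FEATURE_COLUMNS

    path = Path(path)
    if not path.exists():
        raise InputError(f"feature table not found: {path}")
    expected_header = ["id", "label", *FEATURE_COLUMNS]
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != expected_header:
            raise SchemaError(
                f"{path}: header does not match the fixed "
                f"{len(FEATURE_COLUMNS)}-column descriptor schema"
            )
        ids, labels, rows = [], [], []
        for lineno, line in enumerate(handle, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(expected_header):
                raise SchemaError(
                    f"{path}:{lineno}: expected {len(expected_header)} columns, "
                    f"got {len(cells)}"
                )
            ids.append(cells[0])
            labels.append(cells[1])
            try:
                rows.append([float(v) for v in cells[2:]])
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-numeric cell ({exc})")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"{path}: duplicated id(s): {', '.join(dupes)}")
    matrix = np.array(rows, dtype=float) if rows else np.empty((0, len(FEATURE_COLUMNS)))
    return FeatureTable(ids=ids, matrix=matrix, labels=labels)


METRIC_COLUMNS = (
    "repetition",
    "classifier",
    "tp",
    "fp",
    "tn",
    "fn",
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "recall",
    "f_measure",
)


def write_metric_table(metrics: pd.DataFrame, path) -> None:
    """Write the per-repetition metric table as TSV with a fixed schema."""
    missing = [c for c in METRIC_COLUMNS if c not in metrics.columns]
    if missing:
        raise SchemaError(f"metric table missing columns: {missing}")
    metrics.loc[:, METRIC_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_metric_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"metric table not found: {path}")
    return pd.read_csv(path, sep="\t")


def save_model(model, path) -> None:
    """Persist a trained model with a format-version and classifier tag."""
    if model.kind not in CLASSIFIER_KINDS:
        raise SchemaError(f"unknown classifier kind {model.kind!r}")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "classifier_kind": model.kind,
        "estimator": model.estimator,
        "columns": list(model.columns),
        "metadata": dict(model.metadata),
    }
    joblib.dump(payload, path)


def load_model(path):
    from .classify import TrainedModel  # local import: avoid cycle

    path = Path(path)
    if not path.exists():
        raise InputError(f"model file not found: {path}")
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelVersionError(f"{path}: truncated or corrupt model file ({exc})")
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelVersionError(f"{path}: not a recognized model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelVersionError(
            f"{path}: unsupported model format version "
            f"{payload['format_version']!r} (expected {MODEL_FORMAT_VERSION})"
        )
    if payload.get("classifier_kind") not in CLASSIFIER_KINDS:
        raise ModelVersionError(
            f"{path}: unknown classifier kind {payload.get('classifier_kind')!r}"
        )
    return TrainedModel(
        kind=payload["classifier_kind"],
        estimator=payload["estimator"],
        columns=tuple(payload["columns"]),
        metadata=payload["metadata"],
    )
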