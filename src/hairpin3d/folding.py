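"""Secondary-structure prediction for hairpin candidates.

Two engines stand behind one interface:

* ``builtin`` — a Nussinov-style dynamic program that maximizes the number
  of allowed base pairs subject to a minimum hairpin-loop length and the
  non-crossing constraint. Its score is the pair count. The traceback is
  deterministic: among co-optimal structures it prefers leaving the
  rightmost base unpaired, then pairing it with the smallest admissible
  partner.
* ``external`` — an adapter for any RNAfold-compatible thermodynamic
  folder. The command receives FASTA on standard input and must emit
  RNAfold-style output (header, sequence, then ``structure (energy)``).
  Its score is the minimum free energy in kcal/mol.

The built-in engine allows the canonical Watson-Crick pairs plus the G-U
wobble pair by default, and enforces at least ``min_loop`` unpaired bases
inside every hairpin loop (default 3, the physical minimum thermodynamic
folders use). Lonely (isolated) pairs are permitted.
"""

from __future__ import annotations

import re
import shlex
import subprocess
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ExternalFolderError, FoldingBatchError, InputError
from .hairpin_io import SequenceRecord, StructuredRecord

DEFAULT_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


@dataclass(frozen=True)
class FoldingConfig:
    min_loop: int = 3
    allowed_pairs: frozenset = DEFAULT_PAIRS
    engine: str = "builtin"
    external_command: str = "RNAfold --noPS"

    def __post_init__(self):
        if self.min_loop < 0:
            raise InputError("min_loop must be >= 0")
        if not self.allowed_pairs:
            raise InputError("allowed_pairs must be non-empty")
        for x, y in self.allowed_pairs:
            if (y, x) not in self.allowed_pairs:
                raise InputError(f"allowed_pairs not symmetric: {x}{y} without {y}{x}")
        if self.engine not in ("builtin", "external"):
            raise InputError(f"unknown folding engine {self.engine!r}")


def _max_pairing(seq: str, config: FoldingConfig):
    """Nussinov DP: return (pair count, dot-bracket) for one sequence.

    Recurrence over intervals [i, j]:
      N[i][j] = max( N[i][j-1],
                     max over admissible k of N[i][k-1] + N[k+1][j-1] + 1 )
    where k is admissible when (seq[k], seq[j]) is an allowed pair and
    j - k > min_loop. Pairing j against k implicitly covers bifurcation.
    """
    n = len(seq)
    min_loop = config.min_loop
    allowed = config.allowed_pairs
    structure = ["."] * n
    if n < min_loop + 2:
        return 0, "." * n

    # pairable[j] lists admissible partners k < j in increasing order
    pairable = [
        [k for k in range(j - min_loop) if (seq[k], seq[j]) in allowed]
        for j in range(n)
    ]

    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i][j - 1]
            for k in pairable[j]:
                if k < i:
                    continue
                cand = (N[i][k - 1] if k > i else 0) + (
                    N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                ) + 1
                if cand > best:
                    best = cand
            N[i][j] = best

    # Deterministic traceback: prefer j unpaired, then smallest partner k.
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or N[i][j] == 0:
            continue
        if N[i][j] == N[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in pairable[j]:
            if k < i:
                continue
            left = N[i][k - 1] if k > i else 0
            inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
            if left + inner + 1 == N[i][j]:
                structure[k] = "("
                structure[j] = ")"
                if k > i:
                    stack.append((i, k - 1))
                if k + 1 <= j - 1:
                    stack.append((k + 1, j - 1))
                break
    return N[0][n - 1], "".join(structure)


def fold_one(record: SequenceRecord, config: FoldingConfig | None = None) -> StructuredRecord:
    """Predict one secondary structure for ``record``.

    The built-in engine returns the maximum-pairing structure with
    ``score_kind='pair_count'``; the external engine returns the MFE
    structure and energy (``score_kind='energy'``). A sequence too short
    to close any loop returns the all-dots structure, not an error.
    """
    config = config or FoldingConfig()
    if config.engine == "external":
        return _fold_external([record], config)[0]
    score, structure = _max_pairing(record.sequence, config)
    return StructuredRecord(record, structure, float(score), "pair_count")


def fold_many(
    records: Sequence[SequenceRecord], config: FoldingConfig | None = None
) -> list:
    """Fold records elementwise, preserving order.

    Per-record failures are collected and raised together as a
    :class:`FoldingBatchError` naming every failed id.
    """
    config = config or FoldingConfig()
    if config.engine == "external":
        return _fold_external(records, config) if records else []
    out, failures = [], {}
    for rec in records:
        try:
            out.append(fold_one(rec, config))
        except Exception as exc:  # noqa: BLE001 - aggregated and re-raised
            failures[rec.id] = str(exc)
    if failures:
        raise FoldingBatchError(failures)
    return out


_EXT_LINE = re.compile(r"^([.()]+)\s+\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def _fold_external(records: Sequence[SequenceRecord], config: FoldingConfig) -> list:
    fasta = "".join(f">{r.id}\n{r.sequence}\n" for r in records)
    argv = shlex.split(config.external_command)
    try:
        proc = subprocess.run(
            argv, input=fasta, capture_output=True, text=True, check=False
        )
    except FileNotFoundError:
        raise ExternalFolderError(
            f"external folding engine not found: {argv[0]!r}"
        )
    if proc.returncode != 0:
        raise ExternalFolderError(
            f"external folder exited {proc.returncode}: {proc.stderr.strip()[:500]}"
        )
    by_id = {r.id: r for r in records}
    out = []
    lines = [ln.strip() for ln in proc.stdout.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ExternalFolderError(
                f"unparsable external output near: {lines[i]!r}"
            )
        rid = lines[i][1:].split()[0]
        if rid not in by_id or i + 2 >= len(lines):
            raise ExternalFolderError(f"external output misaligned at {rid!r}")
        m = _EXT_LINE.match(lines[i + 2])
        if m is None:
            raise ExternalFolderError(
                f"unparsable structure line for {rid!r}: {lines[i + 2]!r}"
            )
        out.append(
            StructuredRecord(by_id[rid], m.group(1), float(m.group(2)), "energy")
        )
        i += 3
    if len(out) != len(records):
        raise ExternalFolderError(
            f"external folder returned {len(out)} structures for "
            f"{len(records)} records"
        )
    return out


def brute_force_max_pairs(seq: str, config: FoldingConfig | None = None) -> int:
    """Exhaustive maximum over all legal non-crossing pairings.

    Plain recursion with no memoization; exponential, intended as an
    independent oracle for short sequences (length <= ~14) only.
    """
    config = config or FoldingConfig()
    allowed = config.allowed_pairs
    min_loop = config.min_loop

    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        top = best(i, j - 1)  # j unpaired
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in allowed:
                top = max(top, best(i, k - 1) + best(k + 1, j - 1) + 1)
        return top

    return best(0, len(seq) - 1)
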