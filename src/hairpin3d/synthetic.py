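"""Synthetic labeled corpora: miRNA-like hairpins and pseudohairpin decoys.

Positives emulate the shape of real precursors: a complementary stem of
18-30 bp closed by a 4-12 nt loop, with a 10% per-position chance of a
mismatched base on the 3' arm and a 5% per-position chance of a
single-base bulge, at 50% GC. Negatives default to dinucleotide-preserving
shuffles of freshly drawn hairpins (Altschul-Erickson Eulerian-walk
shuffle), which keeps mono- and dinucleotide composition while destroying
the stem — the honest analogue of genomic pseudohairpins, which are
composition-realistic stem-loops rather than random strings. A simpler
``random_matched`` mode (i.i.d. bases at the target GC, length drawn like
a positive) is kept as an easier baseline.

Loop bases are drawn i.i.d. at the target GC; processing-enzyme sequence
motifs are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .hairpin_io import SequenceRecord

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class SynthConfig:
    n_pos: int = 200
    n_neg: int = 200
    seed: int = 0
    stem_len_range: tuple = (18, 30)
    loop_len_range: tuple = (4, 12)
    mismatch_rate: float = 0.10
    bulge_rate: float = 0.05
    gc_content: float = 0.5
    neg_mode: str = "dinucleotide_shuffle"

    def __post_init__(self):
        for lo, hi in (self.stem_len_range, self.loop_len_range):
            if lo > hi or lo < 1:
                raise InputError("length ranges must be non-empty and positive")
        for rate in (self.mismatch_rate, self.bulge_rate):
            if not 0.0 <= rate < 1.0:
                raise InputError("rates must lie in [0, 1)")
        if not 0.0 < self.gc_content < 1.0:
            raise InputError("gc_content must lie in (0, 1)")
        if self.neg_mode not in ("dinucleotide_shuffle", "random_matched"):
            raise InputError(f"unknown neg_mode {self.neg_mode!r}")


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, U
    return "".join(rng.choice(list("ACGU"), size=n, p=p))


def make_hairpin(config: SynthConfig, rng: np.random.Generator) -> str:
    """One miRNA-like hairpin sequence: stem + loop + perturbed revcomp stem."""
    s = int(rng.integers(config.stem_len_range[0], config.stem_len_range[1] + 1))
    l = int(rng.integers(config.loop_len_range[0], config.loop_len_range[1] + 1))
    stem5 = _draw_bases(rng, s, config.gc_content)
    loop = _draw_bases(rng, l, config.gc_content)
    arm3 = []
    for base in reversed(stem5):
        comp = COMPLEMENT[base]
        if rng.random() < config.mismatch_rate:
            comp = str(rng.choice([b for b in "ACGU" if b != COMPLEMENT[base]]))
        arm3.append(comp)
        if rng.random() < config.bulge_rate:
            arm3.append(str(rng.choice(list("ACGU"))))
    return stem5 + loop + "".join(arm3)


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle: permute a sequence preserving all
    dinucleotide (and hence mononucleotide) counts.

    The sequence is viewed as an Eulerian walk on the multigraph whose
    edges are its adjacent base pairs; a uniform random last-edge
    arborescence toward the final base is drawn, the remaining out-edges
    of each base are shuffled, and the walk is replayed. First and last
    base are invariants of the shuffle.
    """
    n = len(sequence)
    if n <= 2:
        return sequence
    vertices = sorted(set(sequence))
    edges = {v: [] for v in vertices}
    for a, b in zip(sequence, sequence[1:]):
        edges[a].append(b)
    last = sequence[-1]

    def pick_arborescence():
        # For each vertex with out-edges (except `last`), pick a candidate
        # final edge; accept when every such vertex reaches `last` by
        # following final edges (the classic rejection step).
        while True:
            final = {}
            for v in vertices:
                if v != last and edges[v]:
                    final[v] = edges[v][int(rng.integers(len(edges[v])))]
            ok = True
            for v in final:
                seen = set()
                cur = v
                while cur != last:
                    if cur in seen or cur not in final:
                        ok = False
                        break
                    seen.add(cur)
                    cur = final[cur]
                if not ok:
                    break
            if ok:
                return final

    final = pick_arborescence()
    pools = {}
    for v in vertices:
        pool = list(edges[v])
        if v in final:
            pool.remove(final[v])
        rng.shuffle(pool)
        if v in final:
            pool.append(final[v])
        pools[v] = pool

    out = [sequence[0]]
    positions = {v: 0 for v in vertices}
    cur = sequence[0]
    for _ in range(n - 1):
        nxt = pools[cur][positions[cur]]
        positions[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def make_pseudohairpin(config: SynthConfig, rng: np.random.Generator) -> str:
    """One decoy sequence per the configured negative mode."""
    if config.neg_mode == "dinucleotide_shuffle":
        return dinucleotide_shuffle(make_hairpin(config, rng), rng)
    # random_matched: i.i.d. bases, length drawn like a positive
    s = int(rng.integers(config.stem_len_range[0], config.stem_len_range[1] + 1))
    l = int(rng.integers(config.loop_len_range[0], config.loop_len_range[1] + 1))
    return _draw_bases(rng, 2 * s + l, config.gc_content)


def make_corpus(config: SynthConfig):
    """Generate (positives, negatives) as SequenceRecord lists.

    Fully determined by ``config.seed``; ids run ``syn_pos_0001`` ... and
    ``syn_neg_0001`` ...
    """
    rng = np.random.default_rng(config.seed)
    pos = [
        SequenceRecord(id=f"syn_pos_{i + 1:04d}", sequence=make_hairpin(config, rng))
        for i in range(config.n_pos)
    ]
    neg = [
        SequenceRecord(
            id=f"syn_neg_{i + 1:04d}", sequence=make_pseudohairpin(config, rng)
        )
        for i in range(config.n_neg)
    ]
    return pos, neg
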