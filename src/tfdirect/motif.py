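"""PWM motif scanning and enrichment against a dinucleotide-shuffled background.

The ETS-family core motif (GGAA/T-centered) ships as the default matrix; any
JASPAR-style count/probability matrix is accepted.  Sequences are scanned on
both strands with a log2-odds score, and enrichment compares the fraction of
peak sequences carrying at least one hit with a size-matched background of
per-sequence dinucleotide shuffles (an Eulerian-path shuffle that preserves
each sequence's dinucleotide counts exactly), via Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str  # + or -
    score: float  # bits


class PWM:
    """Position weight matrix with background-relative log2-odds scores."""

    def __init__(
        self,
        probs: np.ndarray,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        pseudocount: float = 1e-3,
        name: str = "motif",
    ):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM must be W x 4 over A,C,G,T")
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        probs = probs + pseudocount
        probs = probs / probs.sum(axis=1, keepdims=True)
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()
        self.probs = probs
        self.background = bg
        self.log_odds = np.log2(probs / bg)
        self.name = name

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def score_window(self, window: str) -> float:
        """Log2-odds score of one window (must have length == width, ACGT only)."""
        return float(
            sum(self.log_odds[i, _INDEX[b]] for i, b in enumerate(window))
        )

    @classmethod
    def from_jaspar(cls, path: str | Path, **kwargs) -> "PWM":
        """Read a JASPAR-format matrix: >name then 4 rows A/C/G/T of counts."""
        name = "motif"
        rows: dict[str, list[float]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    continue
                base = line[0].upper()
                nums = line[1:].replace("[", " ").replace("]", " ").split()
                rows[base] = [float(x) for x in nums]
        if set(rows) != set(ALPHABET):
            raise ValueError(f"JASPAR matrix must have A,C,G,T rows, got {sorted(rows)}")
        counts = np.array([rows[b] for b in ALPHABET]).T  # W x 4
        probs = counts / counts.sum(axis=1, keepdims=True)
        return cls(probs, name=name, **kwargs)


# ETS core: 5'-ACAGGAAGT-3' style consensus around the invariant GGA(A/T) core.
_ETS_CORE_COUNTS = np.array(
    [
        # A    C    G    T
        [ 60,  15,  15,  10],
        [ 10,  70,  10,  10],
        [ 75,   5,  15,   5],
        [  2,   2,  94,   2],
        [  2,   2,  94,   2],
        [ 90,   2,   4,   4],
        [ 55,   3,   4,  38],
        [  5,   5,  80,  10],
        [ 20,  20,  20,  40],
    ],
    dtype=float,
)


def ets_core_pwm() -> PWM:
    """Default ETS-family core PWM (GGAA/T-centered, width 9)."""
    probs = _ETS_CORE_COUNTS / _ETS_CORE_COUNTS.sum(axis=1, keepdims=True)
    return PWM(probs, name="ETS_core")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Minimal FASTA reader returning (id, sequence) pairs, uppercased."""
    records: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks).upper()))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks).upper()))
    return records


def scan_pwm(
    sequences: Iterable[tuple[str, str]],
    pwm: PWM,
    threshold: float | None = None,
) -> list[MotifHit]:
    """All windows on either strand scoring >= threshold (bits).

    ``threshold`` defaults to 80% of the PWM's maximum achievable score.
    Windows containing N (or any non-ACGT base) are skipped; sequences
    shorter than the motif yield no hits.  Offsets are always on the forward
    strand; a - strand hit at offset i means the reverse complement of
    ``seq[i:i+W]`` matches.
    """
    if threshold is None:
        threshold = 0.8 * pwm.max_score
    W = pwm.width
    hits: list[MotifHit] = []
    for seq_id, seq in sequences:
        seq = seq.upper()
        for offset in range(len(seq) - W + 1):
            window = seq[offset : offset + W]
            if any(b not in _INDEX for b in window):
                continue
            fwd = pwm.score_window(window)
            if fwd >= threshold:
                hits.append(MotifHit(seq_id, offset, "+", fwd))
            rev = pwm.score_window(reverse_complement(window))
            if rev >= threshold:
                hits.append(MotifHit(seq_id, offset, "-", rev))
    return hits


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul-Erikson Eulerian-path shuffle on the dinucleotide transition
    multigraph: a uniformly sampled arborescence toward the terminal base
    fixes each vertex's last outgoing edge, the remaining edges are permuted,
    and the walk from the first base rebuilds a sequence with identical
    mono- and dinucleotide composition.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(edges.keys() | set().union(*map(set, edges.values())))

    # sample a random arborescence toward `last` (Wilson's loop-erased walk)
    for _ in range(200):
        next_in_tree: dict[str, str] = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            # random walk from v until hitting the tree or `last`
            path = [v]
            seen = {v}
            cur = v
            steps = 0
            while cur != last and cur not in next_in_tree:
                outs = edges.get(cur)
                if not outs:
                    ok = False
                    break
                cur = outs[rng.integers(len(outs))]
                steps += 1
                if steps > 10000:
                    ok = False
                    break
                if cur in seen:
                    # loop-erase
                    while path[-1] != cur:
                        seen.discard(path.pop())
                else:
                    seen.add(cur)
                    path.append(cur)
            if not ok:
                break
            for a, b in zip(path, path[1:]):
                next_in_tree[a] = b
        if ok:
            break
    else:  # pragma: no cover - degenerate graphs
        return seq

    shuffled_edges: dict[str, list[str]] = {}
    for v, outs in edges.items():
        outs = list(outs)
        if v != last and v in next_in_tree:
            outs.remove(next_in_tree[v])
            rng.shuffle(outs)
            outs.append(next_in_tree[v])
        else:
            rng.shuffle(outs)
        shuffled_edges[v] = outs

    result = [first]
    counters = {v: 0 for v in shuffled_edges}
    cur = first
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][counters[cur]]
        counters[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)


def enrichment_test(
    peak_sequences: Sequence[tuple[str, str]],
    pwm: PWM,
    threshold: float | None = None,
    *,
    background_sequences: Sequence[tuple[str, str]] | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Fold enrichment and Fisher p of motif occurrence vs background.

    The fraction of sequences with >= 1 hit is compared between peaks and a
    size-matched background (per-sequence dinucleotide shuffles by default).
    Returns (fold, two-sided Fisher exact p); fold is the ratio of hit
    fractions (inf if the background fraction is zero and the peak fraction
    positive, 1 if both are zero).
    """
    if background_sequences is None:
        rng = np.random.default_rng(seed)
        background_sequences = [
            (f"shuf_{sid}", dinucleotide_shuffle(s, rng)) for sid, s in peak_sequences
        ]
    if not background_sequences:
        raise ValueError("empty background")

    def hit_ids(seqs: Sequence[tuple[str, str]]) -> set[str]:
        return {h.sequence_id for h in scan_pwm(seqs, pwm, threshold)}

    k_peak = len(hit_ids(peak_sequences))
    k_bg = len(hit_ids(background_sequences))
    n_peak, n_bg = len(peak_sequences), len(background_sequences)
    table = [[k_peak, n_peak - k_peak], [k_bg, n_bg - k_bg]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    f_peak, f_bg = k_peak / n_peak, k_bg / n_bg
    if f_bg == 0:
        fold = float("inf") if f_peak > 0 else 1.0
    else:
        fold = f_peak / f_bg
    return float(fold), float(p)
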