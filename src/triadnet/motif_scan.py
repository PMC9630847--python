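"""Promoter extraction and PWM scanning with exact score p-values.

TF->gene regulatory edges are called by scanning promoter windows
(by default 1000 bp upstream to 200 bp downstream of the TSS, on the coding
strand) with JASPAR-style position frequency matrices.  Windows on both
strands are scored with a log2 log-odds matrix; the p-value of a score is
the probability that a random background window scores at least as high,
computed exactly by dynamic programming over the integer-discretized score
distribution (bin width 1e-3 on the log-odds scale).  Hits with p below a
threshold (1e-5 by default) call one deduplicated TF->gene edge per
promoter.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .grn_ffl import RegulatoryEdge

__all__ = [
    "PWM",
    "MotifHit",
    "extract_promoter",
    "log_odds_matrix",
    "score_distribution",
    "score_pvalue",
    "scan",
    "call_tf_gene_edges",
    "read_jaspar",
    "write_jaspar",
    "write_hits_tsv",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_PERM = np.array([3, 2, 1, 0])  # A<->T, C<->G
#: bin width for score discretization, on the log2 odds scale
SCORE_BIN = 1e-3
UNIFORM_BG = np.full(4, 0.25)


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over the DNA alphabet.

    ``matrix`` holds per-position base frequencies or counts, shape
    (width, 4) with columns ordered A, C, G, T.  ``pseudocount`` (total per
    column, split proportionally to the background) regularises zero
    frequencies; the default 0.8 follows common PWM-scanning practice.
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PWM matrix must have shape (width, 4), width >= 1")
        if (m < 0).any():
            raise ValueError("PWM entries must be non-negative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def frequencies(self) -> np.ndarray:
        """Pseudocount-regularised per-position base frequencies.

        The total ``pseudocount`` is split across bases proportionally to
        the background and added to each position's counts before
        normalisation: (count + pseudocount * bg) / (total + pseudocount).
        """
        totals = self.matrix.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ValueError("PWM has an all-zero column")
        freq = self.matrix + self.pseudocount * self.background[None, :]
        return freq / freq.sum(axis=1, keepdims=True)

    def raw_frequencies(self) -> np.ndarray:
        """Per-position base frequencies without pseudocount."""
        totals = self.matrix.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ValueError("PWM has an all-zero column")
        return self.matrix / totals

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    """One retained PWM match on a scanned sequence.

    ``start`` is 0-based on the forward strand; the match occupies
    [start, start + width).  ``strand`` is '+' when the forward sequence
    matches the motif, '-' when its reverse complement does.
    """

    seq_id: str
    start: int
    width: int
    strand: str
    score: float
    p_value: float

    @property
    def end(self) -> int:
        return self.start + self.width


def extract_promoter(
    tss: int,
    strand: str,
    genome_seq: str,
    upstream: int = 1000,
    downstream: int = 200,
) -> tuple[str, bool]:
    """Promoter sequence on the coding strand around a TSS.

    For a + gene the window is [tss - upstream, tss + downstream); for a -
    gene it is the reverse complement of [tss - downstream, tss + upstream).
    Windows extending past a contig end are truncated and flagged.

    Returns
    -------
    (sequence, truncated)
    """
    n = len(genome_seq)
    if not 0 <= tss < n:
        raise ValueError(f"TSS {tss} outside contig of length {n}")
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
    elif strand == "-":
        lo, hi = tss - downstream, tss + upstream
    else:
        raise ValueError("strand must be '+' or '-'")
    truncated = lo < 0 or hi > n
    seq = genome_seq[max(lo, 0) : min(hi, n)]
    if strand == "-":
        seq = reverse_complement(seq)
    return seq, truncated


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtN", "TGCAtgcaN"))[::-1]


def log_odds_matrix(pwm: PWM) -> np.ndarray:
    """log2 odds score matrix: log2(frequency / background).

    Finite for pseudocount > 0; with a zero pseudocount, zero-frequency
    cells score -inf (such windows can never be hits).
    """
    with np.errstate(divide="ignore"):
        return np.log2(pwm.frequencies() / pwm.background[None, :])


def _discretize(score_matrix: np.ndarray, bin_width: float = SCORE_BIN) -> np.ndarray:
    """Round scores to integer multiples of ``bin_width``; -inf passes through."""
    out = np.full(score_matrix.shape, np.iinfo(np.int64).min, dtype=np.int64)
    finite = np.isfinite(score_matrix)
    out[finite] = np.rint(score_matrix[finite] / bin_width).astype(np.int64)
    return out


def score_distribution(
    score_matrix: np.ndarray,
    background: np.ndarray | None = None,
    bin_width: float = SCORE_BIN,
) -> tuple[int, np.ndarray]:
    """Exact distribution of the discretized window score under background.

    Dynamic programming over positions: the returned array ``probs`` gives
    P(score == (offset + k) * bin_width) at index k.  Words containing a
    -inf cell carry their probability mass outside the finite support (the
    array sums to < 1 in that case); they can never reach a finite
    threshold.

    Returns
    -------
    (offset, probs) : integer score offset and probability array.
    """
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    disc = _discretize(score_matrix, bin_width)
    neg_inf = np.iinfo(np.int64).min
    probs = np.array([1.0])
    offset = 0
    for pos in range(disc.shape[0]):
        col = disc[pos]
        finite = col != neg_inf
        if not finite.any():
            return 0, np.zeros(1)
        lo, hi = int(col[finite].min()), int(col[finite].max())
        new = np.zeros(probs.size + (hi - lo), dtype=float)
        for b in range(4):
            if finite[b]:
                shift = int(col[b]) - lo
                new[shift : shift + probs.size] += bg[b] * probs
        probs = new
        offset += lo
    return offset, probs


def score_pvalue(
    score_matrix: np.ndarray,
    s: float,
    background: np.ndarray | None = None,
    bin_width: float = SCORE_BIN,
) -> float:
    """P(window score >= s) for a random background window.

    Both the matrix entries and ``s`` are discretized to ``bin_width``
    before comparison, so the value is exact on the discretized scale.  A
    threshold above the maximum attainable score returns exactly 0.0.
    """
    if not np.isfinite(s):
        raise ValueError("threshold score must be finite")
    offset, probs = score_distribution(score_matrix, background, bin_width)
    s_int = int(np.rint(s / bin_width))
    k = s_int - offset
    if k <= 0:
        return float(probs.sum())
    if k >= probs.size:
        return 0.0
    return float(probs[k:].sum())


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to indices 0..3; unknown bases become -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def scan(
    seq: str,
    pwm: PWM,
    threshold_p: float = 1e-5,
    seq_id: str = "seq",
    bin_width: float = SCORE_BIN,
) -> list[MotifHit]:
    """Scan a sequence on both strands, retaining hits with p < threshold.

    All windows of the motif width are scored on the forward strand and,
    via the reverse-complemented score matrix, on the reverse strand; a
    window's p-value comes from the exact background score distribution.
    Hits are sorted by start position (then strand).  A sequence shorter
    than the motif yields no hits.
    """
    lom = log_odds_matrix(pwm)
    if pwm.pseudocount == 0 and not np.isfinite(lom).all():
        raise ValueError("scanning requires pseudocount > 0 (finite scores)")
    w = pwm.width
    offset, probs = score_distribution(lom, pwm.background, bin_width)
    # tail[k] = P(score_int >= offset + k)
    tail = np.concatenate([np.cumsum(probs[::-1])[::-1], [0.0]])
    disc = _discretize(lom, bin_width)
    # reverse strand: scoring revcomp(window) with M == scoring window with
    # M reversed row-wise and complement-permuted column-wise
    disc_rc = disc[::-1][:, _COMPLEMENT_PERM]

    enc = _encode(seq)
    if enc.size < w:
        return []
    hits: list[MotifHit] = []
    valid = enc >= 0
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    window_ok = np.lib.stride_tricks.sliding_window_view(valid, w).all(axis=1)
    pos_idx = np.arange(w)
    for strand, mat in (("+", disc), ("-", disc_rc)):
        scores = mat[pos_idx, windows.clip(min=0)].sum(axis=1)
        for start in np.nonzero(window_ok)[0]:
            k = int(scores[start]) - offset
            p = float(tail[min(max(k, 0), tail.size - 1)]) if k >= 0 else float(
                tail[0]
            )
            if p < threshold_p:
                hits.append(
                    MotifHit(
                        seq_id=seq_id,
                        start=int(start),
                        width=w,
                        strand=strand,
                        score=float(scores[start]) * bin_width,
                        p_value=p,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def call_tf_gene_edges(
    hits_by_tf: Mapping[str, Iterable[MotifHit]],
    gene_map: Mapping[str, str] | None = None,
) -> list[RegulatoryEdge]:
    """Collapse motif hits into deduplicated TF->gene edges.

    One edge is emitted per (TF, promoter) with at least one retained hit;
    its evidence is the best (lowest) hit p-value.  ``gene_map`` translates
    promoter sequence ids to gene ids (identity when omitted).  The result
    is independent of hit order.
    """
    best: dict[tuple[str, str], float] = {}
    for tf, hits in hits_by_tf.items():
        for hit in hits:
            gene = gene_map[hit.seq_id] if gene_map is not None else hit.seq_id
            if tf == gene:
                continue
            key = (tf, gene)
            if key not in best or hit.p_value < best[key]:
                best[key] = hit.p_value
    return [
        RegulatoryEdge(
            regulator=tf,
            regulator_class="TF",
            target=gene,
            target_class="gene",
            evidence=f"motif_p={p:.3g}",
        )
        for (tf, gene), p in sorted(best.items())
    ]


def read_jaspar(path) -> dict[str, PWM]:
    """Read PWMs from a JASPAR-format PFM file (via Bio.motifs)."""
    out: dict[str, PWM] = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            mat = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
            name = m.matrix_id or m.name
            out[name] = PWM(name=name, matrix=mat)
    return out


def write_jaspar(pwms: Sequence[PWM], path) -> None:
    """Write PWMs as JASPAR-format PFMs."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name} {pwm.name}\n")
            for i, base in enumerate(BASES):
                counts = " ".join(f"{v:.2f}" for v in pwm.matrix[:, i])
                fh.write(f"{base}  [ {counts} ]\n")


def write_hits_tsv(hits: Iterable[MotifHit], tf: str, path) -> None:
    """Write hits as a BED-like TSV: seqid, start, end, TF, score, strand, p."""
    with open(path, "w") as fh:
        fh.write("seqid\tstart\tend\ttf\tscore\tstrand\tp_value\n")
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{tf}\t{h.score:.4f}"
                f"\t{h.strand}\t{h.p_value:.6g}\n"
            )
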