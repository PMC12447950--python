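"""TSS-centered windows, motif discovery, scanning and positional enrichment.

This module covers the promoter-motif arm of the pipeline:

* :func:`extract_windows` cuts the sequence ±halfwidth (default 50 kb)
  around each gene's TSS, orienting minus-strand genes so that upstream
  offsets are always negative.
* :func:`fragment_and_label` tiles windows into fixed-size fragments
  (default 100 bp) labeled target or control by gene membership.
* :func:`discover_discriminative_motif` is a deliberately simple
  discriminative discovery procedure: exact-word seeds ranked by a
  one-sided Fisher/hypergeometric enrichment p-value (Bonferroni-corrected
  over all 4^w seeds), with the top seeds extended to PWMs by aligning
  their occurrences with ±2 bp of flank and averaging base frequencies.
* :func:`scan` finds occurrences of a bipartite consensus motif (forward
  half + spacer + reverse-complement half, IUPAC degeneracy, both strands)
  or of a PWM, with PWM p-values computed exactly by dynamic programming
  over the lattice of achievable log-odds scores under a 0-order
  background.
* :func:`positional_enrichment` reproduces the binned (10 bp),
  mean-normalized, smoothed (50 bp rolling window), min-max-scaled
  target/control occurrence-frequency ratio around the TSS.

Coordinates are 0-based half-open throughout; hits are located by motif
start; gene-oriented offsets are negative upstream of the TSS.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .elements import IUPAC, iupac_to_regex

__all__ = [
    "Window",
    "EnhancerFragment",
    "MotifModel",
    "PositionalEnrichmentCurve",
    "extract_windows",
    "fragment_and_label",
    "discover_discriminative_motif",
    "scan",
    "positional_enrichment",
    "hits_to_offsets",
    "revcomp",
]

_COMP = str.maketrans("ACGTN", "TGCAN")
BASES = "ACGT"


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# windows and fragments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    """A gene-oriented TSS-centered sequence window.

    ``seq`` reads in the gene's direction (minus-strand genes are reverse
    complemented). ``offset_of`` maps an oriented position to its signed
    TSS-relative offset, negative upstream.
    """

    gene: str
    contig: str
    tss: int
    strand: str
    start: int  # contig coordinates, 0-based half-open
    end: int
    seq: str

    def offset_of(self, i: int) -> int:
        if self.strand == "+":
            return self.start + i - self.tss
        return self.tss - (self.end - 1 - i)


def extract_windows(annotation: pd.DataFrame, genome: dict[str, str],
                    halfwidth: int = 50_000) -> dict[str, Window]:
    """Extract [TSS−halfwidth, TSS+halfwidth) windows, clipped and oriented.

    ``annotation`` needs columns gene, contig, tss, strand. Raises if a
    gene's contig is missing or its TSS falls outside the contig.
    """
    out: dict[str, Window] = {}
    for row in annotation.itertuples(index=False):
        if row.contig not in genome:
            raise KeyError(f"contig {row.contig!r} (gene {row.gene}) "
                           "not in genome")
        contig_seq = genome[row.contig]
        tss = int(row.tss)
        if not (0 <= tss < len(contig_seq)):
            raise ValueError(f"TSS outside contig for gene {row.gene}")
        start = max(0, tss - halfwidth)
        end = min(len(contig_seq), tss + halfwidth)
        seq = contig_seq[start:end].upper()
        if row.strand == "-":
            seq = revcomp(seq)
        elif row.strand != "+":
            raise ValueError(f"bad strand {row.strand!r} for gene {row.gene}")
        out[row.gene] = Window(row.gene, row.contig, tss, row.strand,
                               start, end, seq)
    return out


@dataclass(frozen=True)
class EnhancerFragment:
    gene: str
    offset: int          # fragment start, signed bp relative to TSS
    seq: str
    label: str           # target | control


def fragment_and_label(windows: dict[str, Window], target_genes,
                       fragment_size: int = 100) -> list[EnhancerFragment]:
    """Tile each window into non-overlapping fragments from its 5' end.

    The terminal remainder shorter than ``fragment_size`` is dropped.
    Fragments of genes in ``target_genes`` are labeled target, all others
    control.
    """
    if fragment_size < 1:
        raise ValueError("fragment_size must be >= 1")
    target_genes = set(target_genes)
    frags: list[EnhancerFragment] = []
    for gene in sorted(windows):
        w = windows[gene]
        label = "target" if gene in target_genes else "control"
        n = len(w.seq) // fragment_size
        for i in range(n):
            s = i * fragment_size
            frags.append(EnhancerFragment(gene, w.offset_of(s),
                                          w.seq[s:s + fragment_size], label))
    return frags


# ---------------------------------------------------------------------------
# motif models
# ---------------------------------------------------------------------------

@dataclass
class MotifModel:
    """A bipartite consensus motif and/or a PWM.

    ``kind == "bipartite"``: IUPAC forward half-site, reverse-complement
    half-site and an inclusive spacer-length range in bp.
    ``kind == "pwm"``: ``probs`` is a width × 4 row-stochastic matrix over
    A, C, G, T and ``background`` the 0-order background distribution; the
    scanning score is the log-odds sum in bits.
    """

    kind: str
    forward: str = "CNNC"
    reverse: str = "GNNG"
    spacer: tuple[int, int] = (0, 10)
    probs: np.ndarray | None = None
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    name: str = "motif"

    def __post_init__(self) -> None:
        if self.kind not in ("bipartite", "pwm"):
            raise ValueError("kind must be 'bipartite' or 'pwm'")
        if self.kind == "bipartite":
            for half in (self.forward, self.reverse):
                for ch in half:
                    if ch not in IUPAC:
                        raise ValueError(f"invalid IUPAC symbol: {ch!r}")
            if self.spacer[0] < 0 or self.spacer[1] < self.spacer[0]:
                raise ValueError("bad spacer range")
        else:
            p = np.asarray(self.probs, dtype=float)
            if p.ndim != 2 or p.shape[1] != 4:
                raise ValueError("PWM must be width x 4")
            if not np.allclose(p.sum(axis=1), 1.0):
                raise ValueError("PWM columns must sum to 1")
            self.probs = p
            self.background = np.asarray(self.background, dtype=float)
            if not np.isclose(self.background.sum(), 1.0):
                raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        if self.kind == "pwm":
            return int(self.probs.shape[0])
        return len(self.forward) + self.spacer[1] + len(self.reverse)

    def log_odds(self, pseudocount: float = 0.0) -> np.ndarray:
        p = self.probs + pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background[None, :])

    def consensus(self) -> str:
        if self.kind == "bipartite":
            mid = "N" * self.spacer[0]
            return self.forward + mid + self.reverse
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    # -- MEME minimal text format ------------------------------------------
    def to_meme(self, path) -> None:
        if self.kind != "pwm":
            raise ValueError("only PWMs serialize to MEME format")
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            fh.write("Background letter frequencies\n")
            fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(
                *self.background))
            fh.write(f"MOTIF {self.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {self.width}\n")
            for row in self.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_meme(cls, path) -> "MotifModel":
        name, rows, bg = "motif", [], np.full(4, 0.25)
        with open(path) as fh:
            lines = fh.read().splitlines()
        i = 0
        while i < len(lines):
            line = lines[i].strip()
            if line.startswith("Background letter frequencies"):
                parts = lines[i + 1].split()
                bg = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
                i += 2
                continue
            if line.startswith("MOTIF"):
                name = line.split()[1]
            if line.startswith("letter-probability matrix"):
                m = re.search(r"w=\s*(\d+)", line)
                w = int(m.group(1))
                for j in range(w):
                    rows.append([float(v) for v in lines[i + 1 + j].split()])
                i += w
            i += 1
        return cls(kind="pwm", probs=np.array(rows), background=bg, name=name)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _bipartite_hits_one_strand(seq: str, motif: MotifModel) -> list[tuple[int, int]]:
    lo, hi = motif.spacer
    wf, wr = len(motif.forward), len(motif.reverse)
    fwd = re.compile(iupac_to_regex(motif.forward))
    rev = re.compile(iupac_to_regex(motif.reverse))
    probe = re.compile(f"(?=({iupac_to_regex(motif.forward)}"
                       f"[ACGTN]{{{lo},{hi}}}"
                       f"{iupac_to_regex(motif.reverse)}))")
    hits = []
    for m in probe.finditer(seq):
        start = m.start()
        for spacer in range(lo, hi + 1):
            end = start + wf + spacer + wr
            if end <= len(seq) and rev.match(seq, start + wf + spacer) \
                    and fwd.match(seq, start):
                hits.append((start, end))
    return hits


def exact_pwm_pvalues(motif: MotifModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of PWM scores under the 0-order background.

    Dynamic programming over the lattice of achievable score sums: each
    partial score accumulates left-to-right exactly as a per-word scan
    would, so achievable scores match word scores bit-for-bit. Returns the
    sorted unique scores and P(score >= s) for each.
    """
    lo = motif.log_odds()
    dist: dict[float, float] = {0.0: 1.0}
    for k in range(lo.shape[0]):
        new: dict[float, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = s + lo[k, b]
                new[key] = new.get(key, 0.0) + p * motif.background[b]
        dist = new
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    sf = np.cumsum(probs[::-1])[::-1]  # P(score >= s)
    return scores, sf


def _pwm_scores(seq_idx: np.ndarray, lo: np.ndarray) -> np.ndarray:
    w = lo.shape[0]
    n = len(seq_idx) - w + 1
    if n <= 0:
        return np.empty(0)
    lo5 = np.hstack([lo, np.full((w, 1), -np.inf)])  # N column
    out = np.zeros(n)
    for k in range(w):
        out = out + lo5[k, seq_idx[k:k + n]]
    return out


_IDX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _IDX[ord(_b)] = _i


def _seq_to_idx(seq: str) -> np.ndarray:
    return _IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]


def scan(sequences: dict[str, str], motif: MotifModel,
         alpha: float = 1e-4, both_strands: bool = True) -> pd.DataFrame:
    """Locate motif occurrences in every sequence.

    Bipartite motifs use exact degenerate matching on both strands, with
    palindromic duplicates collapsed by (sequence, start, span). PWMs are
    scored at every offset on both strands and hits with exact p-value
    <= ``alpha`` are kept. Hits are sorted by sequence then start.
    Columns: seq_id, start, end, strand, score, p_value, matched.
    """
    rows = []
    if motif.kind == "bipartite":
        for sid in sorted(sequences):
            seq = sequences[sid].upper()
            found: dict[tuple[int, int], str] = {}
            for s, e in _bipartite_hits_one_strand(seq, motif):
                found[(s, e)] = "+"
            if both_strands:
                rc = revcomp(seq)
                L = len(seq)
                for s, e in _bipartite_hits_one_strand(rc, motif):
                    key = (L - e, L - s)
                    found.setdefault(key, "-")
            for (s, e), strand in sorted(found.items()):
                rows.append((sid, s, e, strand, np.nan, np.nan, seq[s:e]))
    else:
        lo = motif.log_odds()
        scores_all, sf = exact_pwm_pvalues(motif)
        w = lo.shape[0]

        def pval(s: np.ndarray) -> np.ndarray:
            idx = np.searchsorted(scores_all, s, side="left")
            idx = np.clip(idx, 0, len(scores_all) - 1)
            return sf[idx]

        for sid in sorted(sequences):
            seq = sequences[sid].upper()
            idx = _seq_to_idx(seq)
            for strand, sidx in (("+", idx), ("-", _seq_to_idx(revcomp(seq)))):
                if strand == "-" and not both_strands:
                    continue
                sc = _pwm_scores(sidx, lo)
                finite = np.isfinite(sc)
                if not finite.any():
                    continue
                p = np.full_like(sc, np.nan)
                p[finite] = pval(sc[finite])
                keep = finite & (p <= alpha)
                for i in np.nonzero(keep)[0]:
                    if strand == "+":
                        s, e = int(i), int(i) + w
                    else:
                        s, e = len(seq) - int(i) - w, len(seq) - int(i)
                    rows.append((sid, s, e, strand, float(sc[i]),
                                 float(p[i]), seq[s:e]))
    df = pd.DataFrame(rows, columns=["seq_id", "start", "end", "strand",
                                     "score", "p_value", "matched"])
    return df.sort_values(["seq_id", "start", "end", "strand"],
                          kind="mergesort").reset_index(drop=True)


def hits_to_offsets(hits: pd.DataFrame, windows: dict[str, Window]) -> np.ndarray:
    """Gene-oriented TSS-relative offsets of hit starts."""
    offs = [windows[r.seq_id].offset_of(int(r.start))
            for r in hits.itertuples(index=False)]
    return np.array(offs, dtype=int)


# ---------------------------------------------------------------------------
# discriminative discovery
# ---------------------------------------------------------------------------

def _word_fragment_counts(frags: list[str], width: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in frags:
        seen = {seq[i:i + width] for i in range(len(seq) - width + 1)}
        for wdd in seen:
            if "N" not in wdd:
                counts[wdd] = counts.get(wdd, 0) + 1
    return counts


def _extend_seed_to_pwm(seed: str, frags: list[str], flank: int = 2,
                        pseudocount: float = 0.5,
                        background=None) -> MotifModel:
    """Average base frequencies over the seed's occurrences with flanks."""
    w = len(seed)
    counts = np.zeros((w + 2 * flank, 4))
    for seq in frags:
        for m in re.finditer(f"(?=({seed}))", seq):
            s = m.start() - flank
            if s < 0 or s + w + 2 * flank > len(seq):
                continue
            sub = seq[s:s + w + 2 * flank]
            if "N" in sub:
                continue
            for k, ch in enumerate(sub):
                counts[k, BASES.index(ch)] += 1
    counts += pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return MotifModel(kind="pwm", probs=probs, background=bg, name=seed)


def discover_discriminative_motif(target_frags, control_frags,
                                  widths=range(6, 9), top_n: int = 3,
                                  alpha: float = 0.05) -> list[dict]:
    """Rank exact-word seeds by target-vs-control enrichment.

    For each width, every word present in some fragment is scored by the
    one-sided hypergeometric (Fisher) p-value of the 2×2 table
    (fragments containing the word) × (target/control), Bonferroni
    corrected over all 4^width candidate seeds. The ``top_n`` seeds per
    width are extended to PWMs. Returns a list of dicts sorted by
    corrected p-value with keys consensus, width, p_value, p_corrected,
    n_target, n_control, pwm, significant.
    """
    t_seqs = [f.seq if hasattr(f, "seq") else f for f in target_frags]
    c_seqs = [f.seq if hasattr(f, "seq") else f for f in control_frags]
    if not t_seqs:
        raise ValueError("empty target fragment set")
    if not c_seqs:
        raise ValueError("empty control set: discriminative contrast undefined")
    n_t, n_c = len(t_seqs), len(c_seqs)
    results = []
    for w in widths:
        tc = _word_fragment_counts(t_seqs, w)
        cc = _word_fragment_counts(c_seqs, w)
        words = sorted(tc)
        if not words:
            continue
        a = np.array([tc[wd] for wd in words])
        b = np.array([cc.get(wd, 0) for wd in words])
        # P(X >= a), X = target-containing count under fixed margins
        p = hypergeom.sf(a - 1, n_t + n_c, a + b, n_t)
        bonf = np.minimum(1.0, p * (4.0 ** w))
        order = np.lexsort((words, p))
        for rank_i in order[:top_n]:
            wd = words[rank_i]
            results.append({
                "consensus": wd,
                "width": w,
                "p_value": float(p[rank_i]),
                "p_corrected": float(bonf[rank_i]),
                "n_target": int(a[rank_i]),
                "n_control": int(b[rank_i]),
                "pwm": _extend_seed_to_pwm(wd, t_seqs),
                "significant": bool(bonf[rank_i] < alpha),
            })
    results.sort(key=lambda r: (r["p_corrected"], r["p_value"], r["consensus"]))
    return results


# ---------------------------------------------------------------------------
# positional enrichment
# ---------------------------------------------------------------------------

@dataclass
class PositionalEnrichmentCurve:
    bin_centers: np.ndarray
    f_target: np.ndarray
    f_control: np.ndarray
    ratio: np.ndarray
    eps: float

    @property
    def argmax_offset(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.ratio))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers,
                             "f_target": self.f_target,
                             "f_control": self.f_control,
                             "ratio": self.ratio})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _normalize_series(counts: np.ndarray, smooth_bins: int) -> np.ndarray:
    x = counts.astype(float)
    mean = x.mean()
    if mean > 0:
        x = x / mean
    x = pd.Series(x).rolling(smooth_bins, center=True,
                             min_periods=1).mean().to_numpy()
    lo, hi = x.min(), x.max()
    return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)


def positional_enrichment(target_offsets, control_offsets,
                          halfwidth: int = 50_000, bin_size: int = 10,
                          smooth_bp: int = 50,
                          eps: float = 1e-6) -> PositionalEnrichmentCurve:
    """Target-vs-control positional occurrence enrichment around the TSS.

    Hit offsets (motif starts, gene-oriented) are counted into ``bin_size``
    bp bins tiling [−halfwidth, +halfwidth); each series is divided by its
    mean, smoothed with a centered ``smooth_bp`` rolling mean (shrinking at
    the edges) and min-max scaled to [0, 1]; the per-bin ratio is
    (f_target + eps) / (f_control + eps).
    """
    t = np.asarray(target_offsets, dtype=float)
    c = np.asarray(control_offsets, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("empty target or control hit set")
    edges = np.arange(-halfwidth, halfwidth + bin_size, bin_size, dtype=float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    smooth_bins = max(1, int(round(smooth_bp / bin_size)))
    ft = _normalize_series(np.histogram(t, bins=edges)[0], smooth_bins)
    fc = _normalize_series(np.histogram(c, bins=edges)[0], smooth_bins)
    ratio = (ft + eps) / (fc + eps)
    return PositionalEnrichmentCurve(centers, ft, fc, ratio, eps)
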