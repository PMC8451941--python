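"""Extended half-site motif machinery.

Esrrb and Nr5a2 bind a 9-bp extended oestrogen-response half-site,
TCAAGG(T/C)CA, whose seventh base discriminates the preference of the two
receptors (T favours Esrrb, C favours Nr5a2). This module scans sequences
for the two variant consensi with up to one mismatch, for the trimmed
consensus TCAAGGXCA with complete freedom at the seventh base, and scores
windows against position weight matrices. It also classifies regions by
variant content and computes seventh-base frequency profiles along regions
ranked by relative binding of the two receptors.

Conventions
-----------
* Hit ``offset`` is always the leftmost base of the match on the region's
  + strand, regardless of hit strand.
* ``seventh_base`` is the base read at motif position 7 in motif
  orientation (i.e. complemented for - strand hits).
* ``N`` in the sequence never matches any constrained consensus position.
* Overlapping hits are all reported; no masking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import MotifMatrix, reverse_complement

HALF_SITE_T = "TCAAGGTCA"
HALF_SITE_C = "TCAAGGCCA"
TRIMMED_HALF_SITE = "TCAAGGNCA"  # N = unconstrained seventh base
SEVENTH_POS = 6  # 0-based index of the discriminating base

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DEC = "ACGTN"


class ScanParameterError(ValueError):
    pass


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence within a region."""

    region_id: str
    offset: int
    strand: str
    mismatches: int
    score: float
    seventh_base: str
    motif_name: str


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        out[arr == ord(base)] = code
    return out


def _windows(enc: np.ndarray, m: int) -> np.ndarray:
    if len(enc) < m:
        return np.empty((0, m), dtype=enc.dtype)
    return np.lib.stride_tricks.sliding_window_view(enc, m)


def _mismatch_counts(enc: np.ndarray, cons: str) -> np.ndarray:
    """Hamming distance of every window to a consensus; 'N' in the
    consensus is a wildcard, 'N' in the sequence always mismatches
    constrained positions."""
    m = len(cons)
    win = _windows(enc, m)
    if win.shape[0] == 0:
        return np.empty(0, dtype=int)
    ccode = np.array([_ENC[b] for b in cons], dtype=np.int8)
    free = ccode == 4
    mism = (win != ccode[None, :])
    mism[:, free] = False
    return mism.sum(axis=1)


def _seventh(seq: str, offset: int, strand: str, m: int) -> str:
    """Base at motif position 7 read in motif orientation."""
    if m <= SEVENTH_POS:
        return "other"
    if strand == "+":
        base = seq[offset + SEVENTH_POS]
    else:
        base = seq[offset + (m - 1 - SEVENTH_POS)]
        base = reverse_complement(base)
    return base if base in "TC" else ("other" if base in "AGN" else "other")


def scan_consensus(seq: str, consensus: str, max_mismatch: int = 0,
                   both_strands: bool = True, region_id: str = "",
                   motif_name: str | None = None) -> list[MotifHit]:
    """Report every window within ``max_mismatch`` Hamming distance of the
    consensus, on the + strand and (optionally) the - strand.

    A position holding ``N`` in the consensus is unconstrained and never
    counts toward the mismatch total.
    """
    if not consensus:
        raise ScanParameterError("empty consensus")
    if max_mismatch not in (0, 1):
        raise ScanParameterError("max_mismatch must be 0 or 1")
    consensus = consensus.upper()
    seq = seq.upper()
    m = len(consensus)
    enc = _encode(seq)
    name = motif_name if motif_name is not None else consensus
    hits: list[MotifHit] = []

    fwd = _mismatch_counts(enc, consensus)
    rev = _mismatch_counts(enc, reverse_complement(consensus)) if both_strands else None

    for off in np.nonzero(fwd <= max_mismatch)[0] if fwd.size else []:
        hits.append(MotifHit(region_id, int(off), "+", int(fwd[off]), float("nan"),
                             _seventh(seq, int(off), "+", m), name))
    if rev is not None and rev.size:
        for off in np.nonzero(rev <= max_mismatch)[0]:
            hits.append(MotifHit(region_id, int(off), "-", int(rev[off]), float("nan"),
                                 _seventh(seq, int(off), "-", m), name))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_trimmed_halfsite(seq: str, max_mismatch: int = 0, both_strands: bool = True,
                          region_id: str = "") -> list[MotifHit]:
    """Scan for TCAAGGXCA: the half-site trimmed to leave complete freedom
    at the seventh base, which is excluded from the mismatch count.

    ``seventh_base`` on each hit reports the actual base at position 7 in
    motif orientation (``T``, ``C`` or ``other``).
    """
    return scan_consensus(seq, TRIMMED_HALF_SITE, max_mismatch=max_mismatch,
                          both_strands=both_strands, region_id=region_id,
                          motif_name="halfsite")


def score_pwm(seq: str, motif: MotifMatrix, background: Sequence[float] | None = None,
              region_id: str = "", min_score: float | None = None) -> list[MotifHit]:
    """Log-odds score of every window on both strands.

    The score is the per-position sum of log2(p/background) with the
    motif's pseudocount-adjusted probabilities. ``N`` bases receive the
    minimum score of their column. No threshold is applied unless
    ``min_score`` is given.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if np.any(bg <= 0):
        raise ScanParameterError("background frequencies must be positive")
    lo = motif.log_odds(bg)  # (L, 4)
    lo5 = np.column_stack([lo, lo.min(axis=1)])  # N -> column minimum
    m = motif.length
    seq = seq.upper()
    enc = _encode(seq)
    win = _windows(enc, m)
    hits: list[MotifHit] = []
    if win.shape[0] == 0:
        return hits
    pos_idx = np.arange(m)
    fwd_scores = lo5[pos_idx[None, :], win].sum(axis=1)
    # - strand: score the reverse complement of each window, i.e. score the
    # forward window against the reverse-complemented matrix.
    lo_rc = lo5[::-1, [3, 2, 1, 0, 4]]
    rev_scores = lo_rc[pos_idx[None, :], win].sum(axis=1)
    for off in range(win.shape[0]):
        for strand, sc in (("+", fwd_scores[off]), ("-", rev_scores[off])):
            if min_score is not None and sc <= min_score:
                continue
            hits.append(MotifHit(region_id, off, strand, 0, float(sc),
                                 _seventh(seq, off, strand, m) if m > SEVENTH_POS else "other",
                                 motif.name))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_regions(genome: Mapping[str, str], regions, scanner, **kwargs) -> dict[str, list[MotifHit]]:
    """Apply a scanning function to the sequence of every region.

    ``scanner`` is one of the scan_*/score_pwm functions; extra keyword
    arguments are forwarded. Returns a mapping region id -> hits.
    """
    out: dict[str, list[MotifHit]] = {}
    for iv in regions:
        seq = genome[iv.chrom][iv.start:iv.end]
        out[iv.id] = scanner(seq, region_id=iv.id, **kwargs)
    return out


def classify_regions_by_variant(hits_by_region: Mapping[str, Iterable[MotifHit]],
                                region_ids: Sequence[str]) -> dict[str, str]:
    """Assign each region to {T_only, C_only, both, none} from the seventh
    base of its trimmed-half-site hits.

    A region is ``both`` when it carries at least one T-labelled and one
    C-labelled hit; hits whose seventh base is neither T nor C do not
    contribute. Every region in ``region_ids`` gets exactly one label.
    """
    known = set(region_ids)
    extra = set(hits_by_region) - known
    if extra:
        raise ValueError(f"hits reference unknown regions: {sorted(extra)[:5]}")
    out = {}
    for rid in region_ids:
        bases = {h.seventh_base for h in hits_by_region.get(rid, ())}
        has_t, has_c = "T" in bases, "C" in bases
        out[rid] = ("both" if has_t and has_c
                    else "T_only" if has_t
                    else "C_only" if has_c
                    else "none")
    return out


def seventh_base_frequency_profile(ranked_region_ids: Sequence[str],
                                   hits_by_region: Mapping[str, Iterable[MotifHit]],
                                   window: int, mode: str = "tiled") -> pd.DataFrame:
    """Seventh-base variant frequencies in windows of rank-ordered regions.

    ``ranked_region_ids`` must already be ordered (e.g. by decreasing
    Esrrb/Nr5a2 binding ratio). For each window of ``window`` consecutive
    regions the fraction of trimmed-half-site hits with seventh base T and
    C is reported; freq_T + freq_C <= 1 with the remainder 'other'.
    ``mode`` is ``tiled`` (non-overlapping) or ``sliding`` (step 1).
    """
    n = len(ranked_region_ids)
    if window < 1 or window > n:
        raise ScanParameterError(f"window must be in [1, {n}]")
    if mode not in ("tiled", "sliding"):
        raise ScanParameterError("mode must be 'tiled' or 'sliding'")
    t_counts = np.zeros(n)
    c_counts = np.zeros(n)
    tot = np.zeros(n)
    for i, rid in enumerate(ranked_region_ids):
        for h in hits_by_region.get(rid, ()):
            tot[i] += 1
            if h.seventh_base == "T":
                t_counts[i] += 1
            elif h.seventh_base == "C":
                c_counts[i] += 1
    starts = range(0, n - window + 1, window if mode == "tiled" else 1)
    rows = []
    for w, s in enumerate(starts):
        sl = slice(s, s + window)
        tw, cw, nw = t_counts[sl].sum(), c_counts[sl].sum(), tot[sl].sum()
        rows.append({
            "window": w,
            "rank_start": s,
            "rank_end": s + window,
            "n_hits": int(nw),
            "freq_T": tw / nw if nw else np.nan,
            "freq_C": cw / nw if nw else np.nan,
        })
    return pd.DataFrame(rows)


def binding_ratio(rpm_a: np.ndarray, rpm_b: np.ndarray, pseudo: float = 0.5) -> np.ndarray:
    """log2 ratio of two normalised binding signals with a pseudo-count.

    Used to rank regions by relative Esrrb vs Nr5a2 binding; the
    pseudo-count (default 0.5 RPM) guards against division by zero.
    """
    return np.log2((np.asarray(rpm_a, float) + pseudo) /
                   (np.asarray(rpm_b, float) + pseudo))


def hits_to_table(hits_by_region: Mapping[str, Iterable[MotifHit]]) -> pd.DataFrame:
    rows = [
        {"region_id": h.region_id, "offset": h.offset, "strand": h.strand,
         "mismatches": h.mismatches, "score": h.score,
         "seventh_base": h.seventh_base, "motif_name": h.motif_name}
        for rid in sorted(hits_by_region) for h in hits_by_region[rid]
    ]
    return pd.DataFrame(rows, columns=["region_id", "offset", "strand", "mismatches",
                                       "score", "seventh_base", "motif_name"])


def table_to_hits(df: pd.DataFrame) -> dict[str, list[MotifHit]]:
    out: dict[str, list[MotifHit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.region_id, []).append(MotifHit(
            row.region_id, int(row.offset), row.strand, int(row.mismatches),
            float(row.score), row.seventh_base, row.motif_name))
    return out
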