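"""Motif models and scanning.

Two motif representations are supported:

* an IUPAC consensus string (e.g. the RBPJ consensus ``TTCCCACR``, i.e.
  TTCCCAC followed by A or G), matched exactly per position;
* a position weight matrix (PWM) given as per-base counts or probabilities,
  scored as log-odds against a uniform background with a threshold expressed
  as a fraction of the maximum achievable score (default 0.8).

Matches on the minus strand are reported in plus-strand coordinates. ``N``
in a sequence never matches a non-N consensus code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, FormatError, MitobookError

RBPJ_CONSENSUS = "TTCCCACR"
#: Synthetic 12-bp CTCF-like consensus used by the generator and fixtures;
#: it is the core of a printed CTCF-motif EMSA oligo, not a measured matrix.
CTCF_LIKE_CONSENSUS = "CCACTAGGGGGC"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    name: str
    consensus: str | None = None
    pwm: np.ndarray | None = None  # shape (4, L), row order A,C,G,T
    threshold_fraction: float = 0.8
    both_strands: bool = True

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.pwm is None):
            raise ConfigError("provide exactly one of consensus or pwm")
        if self.consensus is not None:
            self.consensus = self.consensus.upper()
            bad = set(self.consensus) - set(IUPAC)
            if bad:
                raise ConfigError(f"invalid IUPAC code(s) {sorted(bad)} in {self.name}")
        else:
            pwm = np.asarray(self.pwm, dtype=float)
            if pwm.ndim != 2 or pwm.shape[0] != 4 or pwm.shape[1] < 1:
                raise ConfigError("PWM must have shape (4, L)")
            if np.any(pwm < 0) or np.any(pwm.sum(axis=0) <= 0):
                raise ConfigError("PWM columns must have non-negative, non-zero mass")
            self.pwm = pwm / pwm.sum(axis=0, keepdims=True)

    @property
    def length(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[1]

    def log_odds(self, pseudo: float = 1e-3) -> np.ndarray:
        p = (self.pwm + pseudo) / (self.pwm + pseudo).sum(axis=0, keepdims=True)
        return np.log2(p / 0.25)


@dataclass(frozen=True)
class MotifMatch:
    sequence_id: str
    start: int  # 0-based, plus-strand coordinates
    strand: str  # '+' or '-'
    matched: str  # plus-strand substring at [start, start+len)
    score: float | None = None

    @property
    def midpoint(self) -> float:
        return self.start + len(self.matched) / 2.0


def _consensus_regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in consensus
    )
    return re.compile(f"(?=({body}))")


def scan_iupac(
    sequence: str,
    motif: MotifModel,
    both_strands: bool | None = None,
    sequence_id: str = "",
    offset: int = 0,
) -> list[MotifMatch]:
    """All positions where the IUPAC consensus matches.

    Minus-strand hits are found by scanning the forward sequence with the
    reverse-complemented consensus, so their coordinates are already in
    plus-strand space. ``offset`` shifts reported starts (for window scans).
    """
    if motif.consensus is None:
        raise MitobookError("scan_iupac requires a consensus motif")
    if both_strands is None:
        both_strands = motif.both_strands
    seq = sequence.upper()
    out = [
        MotifMatch(sequence_id, m.start() + offset, "+", m.group(1))
        for m in _consensus_regex(motif.consensus).finditer(seq)
    ]
    if both_strands:
        rc = _consensus_regex(reverse_complement(motif.consensus))
        plus_starts = {m.start for m in out}
        for m in rc.finditer(seq):
            # a palindromic hit is the same genomic element; report once
            if motif.consensus == reverse_complement(motif.consensus) and m.start() + offset in plus_starts:
                continue
            out.append(MotifMatch(sequence_id, m.start() + offset, "-", m.group(1)))
    out.sort(key=lambda m: (m.start, m.strand))
    return out


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def scan_pwm(
    sequence: str,
    motif: MotifModel,
    both_strands: bool | None = None,
    sequence_id: str = "",
    offset: int = 0,
) -> list[MotifMatch]:
    """PWM scan; keeps windows scoring >= threshold_fraction * max score."""
    if motif.pwm is None:
        raise MitobookError("scan_pwm requires a PWM motif")
    if both_strands is None:
        both_strands = motif.both_strands
    lo = motif.log_odds()
    L = motif.length
    seq = sequence.upper()
    n = len(seq) - L + 1
    if n <= 0:
        return []
    idx = np.array([_BASE_INDEX.get(c, -1) for c in seq], dtype=np.int64)
    threshold = motif.threshold_fraction * lo.max(axis=0).sum()
    out: list[MotifMatch] = []
    for strands, mat in ((["+"], lo), (["-"], lo[::-1, ::-1])):
        if strands == ["-"] and not both_strands:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(idx, L)
        valid = (windows >= 0).all(axis=1)
        scores = np.full(n, -np.inf)
        cols = np.arange(L)
        ok = np.nonzero(valid)[0]
        if len(ok):
            scores[ok] = mat[windows[ok], cols].sum(axis=1)
        for i in np.nonzero(scores >= threshold)[0]:
            out.append(
                MotifMatch(sequence_id, int(i) + offset, strands[0],
                           seq[i:i + L], float(scores[i]))
            )
    out.sort(key=lambda m: (m.start, m.strand))
    return out


def scan(sequence: str, motif: MotifModel, **kw) -> list[MotifMatch]:
    if motif.consensus is not None:
        return scan_iupac(sequence, motif, **kw)
    return scan_pwm(sequence, motif, **kw)


@dataclass
class MotifContingencyTable:
    """Table-style motif content of one peak class.

    Satisfies inclusion–exclusion: either == with_first + with_second - with_both.
    """

    label: str
    n_peaks: int
    with_first: int
    with_second: int
    with_both: int
    first_name: str
    second_name: str
    centering: str = "own"

    @property
    def with_either(self) -> int:
        return self.with_first + self.with_second - self.with_both

    def validate(self) -> None:
        ok = (
            0 <= self.with_both <= min(self.with_first, self.with_second)
            and max(self.with_first, self.with_second, self.with_either) <= self.n_peaks
        )
        if not ok:
            raise MitobookError("inconsistent contingency table")

    def as_dict(self) -> dict:
        return {
            "class": self.label,
            "n_peaks": self.n_peaks,
            self.first_name: self.with_first,
            self.second_name: self.with_second,
            "either": self.with_either,
            "both": self.with_both,
            "centering": self.centering,
        }


def _window(center: int, half_width: int, length: int) -> tuple[int, int]:
    return max(0, center - half_width), min(length, center + half_width)


def peak_motif_content(
    centers_by_chrom: dict[str, list[int]],
    sequences: dict[str, str],
    first: MotifModel,
    second: MotifModel,
    half_width: int = 100,
    label: str = "",
    centering: str = "own",
) -> MotifContingencyTable:
    """Count peaks whose window around the chosen center contains each motif.

    ``centers_by_chrom`` maps chromosome -> peak centers; the scanned window
    is [center - half_width, center + half_width), truncated at chromosome
    ends.
    """
    n = n1 = n2 = nboth = 0
    for chrom, centers in centers_by_chrom.items():
        seq = sequences[chrom]
        for c in centers:
            s, e = _window(int(c), half_width, len(seq))
            win = seq[s:e]
            h1 = bool(scan(win, first))
            h2 = bool(scan(win, second))
            n += 1
            n1 += h1
            n2 += h2
            nboth += h1 and h2
    table = MotifContingencyTable(label, n, n1, n2, nboth, first.name, second.name,
                                  centering=centering)
    table.validate()
    return table


def genome_match_starts(sequences: dict[str, str], motif: MotifModel) -> dict[str, np.ndarray]:
    """Sorted match-start arrays per chromosome (both strands), for fast
    window-containment queries."""
    return {
        chrom: np.array(sorted({m.start for m in scan(seq, motif)}), dtype=np.int64)
        for chrom, seq in sequences.items()
    }


def motif_enrichment(
    centers_by_chrom: dict[str, list[int]],
    sequences: dict[str, str],
    motif: MotifModel,
    n_resamples: int = 200,
    seed: int = 0,
    half_width: int = 100,
) -> dict:
    """Known-motif enrichment against length-matched resampled windows.

    observed = fraction of peak windows containing >=1 motif match;
    null     = same statistic over ``n_resamples`` draws of equally many
               windows placed uniformly on the genome, excluding windows
               overlapping any peak window;
    p        = (1 + #{null >= observed}) / (1 + n_resamples)  (resolution
               floor 1/(1+n_resamples));
    fold     = observed / mean(null).
    """
    if n_resamples < 100:
        raise ConfigError("n_resamples must be >= 100")
    rng = np.random.default_rng(seed)
    starts = genome_match_starts(sequences, motif)
    L = motif.length

    def window_has_match(chrom: str, s: int, e: int) -> bool:
        arr = starts[chrom]
        lo = np.searchsorted(arr, s, "left")
        hi = np.searchsorted(arr, e - L + 1, "left")
        return hi > lo

    peak_windows: dict[str, list[tuple[int, int]]] = {}
    n_peaks = 0
    hits = 0
    for chrom, centers in centers_by_chrom.items():
        seq_len = len(sequences[chrom])
        for c in centers:
            s, e = _window(int(c), half_width, seq_len)
            peak_windows.setdefault(chrom, []).append((s, e))
            n_peaks += 1
            hits += window_has_match(chrom, s, e)
    if n_peaks == 0:
        raise MitobookError("no peaks to test")
    observed = hits / n_peaks

    chroms = sorted(sequences)
    lengths = np.array([len(sequences[c]) for c in chroms], dtype=float)
    usable = lengths - 2 * half_width
    if np.any(usable <= 0) or usable.sum() < 10 * n_peaks * 2 * half_width:
        raise MitobookError("genome too small for background resampling")
    weights = usable / usable.sum()

    def overlaps_peak(chrom: str, s: int, e: int) -> bool:
        return any(s < pe and ps < e for ps, pe in peak_windows.get(chrom, ()))

    null = np.empty(n_resamples)
    for r in range(n_resamples):
        h = 0
        drawn = 0
        guard = 0
        while drawn < n_peaks:
            ci = rng.choice(len(chroms), p=weights)
            chrom = chroms[ci]
            c = int(rng.integers(half_width, len(sequences[chrom]) - half_width))
            s, e = c - half_width, c + half_width
            guard += 1
            if overlaps_peak(chrom, s, e):
                if guard > 100 * n_peaks:
                    raise MitobookError("background sampling space exhausted")
                continue
            h += window_has_match(chrom, s, e)
            drawn += 1
        null[r] = h / n_peaks

    p = (1 + int(np.sum(null >= observed))) / (1 + n_resamples)
    mean_null = float(null.mean())
    fold = observed / mean_null if mean_null > 0 else float("inf")
    return {
        "observed_fraction": observed,
        "null_mean_fraction": mean_null,
        "p_value": p,
        "fold": fold,
        "n_peaks": n_peaks,
        "n_resamples": n_resamples,
    }


def motif_center_offset(center: float, matches: list[MotifMatch]) -> float | None:
    """Signed offset (bp) of the nearest match midpoint from the peak center.

    Negative means the motif lies left of the center. None if no match.
    """
    if not matches:
        return None
    best = min(matches, key=lambda m: abs(m.midpoint - center))
    return best.midpoint - center


def read_jaspar_matrix(path: str) -> MotifModel:
    """Read a JASPAR-style plain-count matrix.

    Accepts the ``>name`` header followed by four lines, either bare counts
    or the bracketed ``A [ 1 2 3 ]`` form, in A/C/G/T order.
    """
    name = "pwm"
    rows: list[list[float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] or name
                continue
            line = re.sub(r"^[ACGTacgt]\s*\[", "", line)
            line = line.rstrip("]").strip()
            rows.append([float(x) for x in line.split()])
    if len(rows) != 4:
        raise FormatError(f"expected 4 matrix rows (A,C,G,T), found {len(rows)}", path=path)
    return MotifModel(name=name, pwm=np.array(rows))
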