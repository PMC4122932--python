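"""Windowed summary statistics of haplotype samples.

Statistics per 10-kb (by default) window of an ``n``-chromosome sample:

* ``S`` — segregating sites; ``pi`` — mean pairwise differences.
* Tajima's ``D`` and the variance-standardized ``H_FW`` (Fay & Wu) and ``E``
  (Zeng et al.) statistics, three contrasts of scaled-mutation-rate
  estimators that weight different parts of the site frequency spectrum
  (``H_FW`` and ``E`` require derived/ancestral polarization).
* ``K`` — distinct haplotypes; ``H = 1 - sum p_i^2`` — haplotype diversity;
  ``M`` — count of the modal haplotype.

The haplotype-configuration statistic

    ksk(n)^2 = (1/n) * sum_i (K_i - S_i) / K_i^2

averaged over ``n`` contiguous windows is strongly negative when few but
mutually divergent haplotypes dominate (small K, large S) — the signature of
selection on a highly mutable microsatellite, where the favored allele
recurrently mutates onto divergent haplotype backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HaplotypeSample",
    "HaplotypeWindow",
    "WindowStats",
    "KskProfile",
    "window_stats",
    "windows_from_sample",
    "ksk_stat",
    "sliding_ksk",
    "fine_scan",
    "pairwise_diff_matrix",
    "stats_table",
]


@dataclass
class HaplotypeSample:
    """A phased sample of ``n`` chromosomes over a sequence of length ``L`` bp.

    ``matrix`` is n x S_total (0 ancestral / 1 derived when ``polarized``),
    ``positions`` the bp coordinate of each column (0-based, strictly
    increasing).  Monomorphic columns are allowed here; they are dropped when
    windows are cut.
    """

    matrix: np.ndarray
    positions: np.ndarray
    sequence_length: float
    polarized: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.matrix.shape[1] != self.positions.size:
            raise ValueError("matrix columns and positions disagree")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")

    @property
    def num_chromosomes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class HaplotypeWindow:
    """Binary haplotype matrix restricted to one genomic window.

    Monomorphic columns are dropped on construction, so every column
    segregates; ``interval`` is 0-based half-open in bp.
    """

    matrix: np.ndarray
    positions: np.ndarray
    interval: tuple[float, float]
    polarized: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=float)
        n = self.matrix.shape[0]
        if n < 1:
            raise ValueError("window needs at least one chromosome")
        counts = self.matrix.sum(axis=0)
        keep = (counts > 0) & (counts < n)
        if not np.all(keep):
            self.matrix = self.matrix[:, keep]
            self.positions = self.positions[keep]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.interval[0] + self.interval[1])


@dataclass
class WindowStats:
    """Summary statistics of one window (see module docstring)."""

    S: int
    pi: float
    D: float
    H_FW: float
    E: float
    fay_wu_h_raw: float
    K: int
    H: float
    M: int
    n: int
    interval: tuple[float, float] = (0.0, 0.0)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.interval[0] + self.interval[1])


def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def _tajima_d(S: int, pi: float, n: int) -> float:
    if S == 0:
        return np.nan
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi - S / a1) / np.sqrt(var)


def _zeng_statistics(counts: np.ndarray, n: int) -> tuple[float, float, float]:
    """Variance-standardized H_FW and E plus the raw theta_pi - theta_H contrast.

    Uses the normalizations of Zeng et al. (2006): both statistics contrast
    theta_L = sum(i * xi_i) / (n - 1) with theta_pi (H_FW) or Watterson's
    theta_W (E); theta and theta^2 in the variance formulas are estimated by
    S/a_n and S(S-1)/(a_n^2 + b_n).
    """
    S = counts.size
    if S == 0:
        return np.nan, np.nan, np.nan
    a_n, b_n = _harmonics(n)
    b_n1 = b_n + 1.0 / n**2  # sum_{i=1}^{n} 1/i^2
    theta_pi = float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))
    theta_L = float(np.sum(counts) / (n - 1))
    theta_H = float(np.sum(2.0 * counts.astype(float) ** 2) / (n * (n - 1)))
    theta_W = S / a_n
    theta_hat = theta_W
    theta2_hat = S * (S - 1) / (a_n**2 + b_n)
    var_pi_L = (
        theta_hat * (n - 2) / (6.0 * (n - 1))
        + theta2_hat
        * (18 * n**2 * (3 * n + 2) * b_n1 - (88 * n**3 + 9 * n**2 - 13 * n + 6))
        / (9.0 * n * (n - 1) ** 2)
    )
    var_L_W = (
        theta_hat * (n / (2.0 * (n - 1)) - 1.0 / a_n)
        + theta2_hat
        * (
            b_n / a_n**2
            + 2 * (n / (n - 1.0)) ** 2 * b_n
            - 2 * (n * b_n - n + 1) / ((n - 1.0) * a_n)
            - (3 * n + 1) / (n - 1.0)
        )
    )
    h_fw = (theta_pi - theta_L) / np.sqrt(var_pi_L) if var_pi_L > 0 else np.nan
    e = (theta_L - theta_W) / np.sqrt(var_L_W) if var_L_W > 0 else np.nan
    return h_fw, e, theta_pi - theta_H


def haplotype_counts(matrix: np.ndarray) -> np.ndarray:
    """Multiplicities of the distinct rows of a binary haplotype matrix."""
    if matrix.shape[1] == 0:
        return np.array([matrix.shape[0]])
    _, counts = np.unique(np.ascontiguousarray(matrix), axis=0, return_counts=True)
    return counts


def window_stats(win: HaplotypeWindow) -> WindowStats:
    """All window statistics for one ``HaplotypeWindow`` (n >= 2 chromosomes)."""
    n = win.n
    if n < 2:
        raise ValueError("window statistics need at least 2 chromosomes")
    S = win.matrix.shape[1]
    counts = win.matrix.sum(axis=0)
    if S == 0:
        return WindowStats(S=0, pi=0.0, D=np.nan, H_FW=np.nan, E=np.nan,
                           fay_wu_h_raw=np.nan, K=1, H=0.0, M=n, n=n,
                           interval=win.interval)
    pi = float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))
    D = _tajima_d(S, pi, n)
    if win.polarized:
        h_fw, e, h_raw = _zeng_statistics(counts, n)
    else:
        h_fw = e = h_raw = np.nan
    k_counts = haplotype_counts(win.matrix)
    K = int(k_counts.size)
    freqs = k_counts / n
    H = float(1.0 - np.sum(freqs**2))
    M = int(k_counts.max())
    return WindowStats(S=S, pi=pi, D=D, H_FW=h_fw, E=e, fay_wu_h_raw=h_raw,
                       K=K, H=H, M=M, n=n, interval=win.interval)


def windows_from_sample(
    sample: HaplotypeSample,
    window_bp: float = 10_000,
    start: float = 0.0,
    end: float | None = None,
) -> list[HaplotypeWindow]:
    """Cut a sample into nonoverlapping windows of ``window_bp``.

    Windows tile ``[start, end)``; ``end`` defaults to the sequence length.
    Windows with no variants are returned (they have S = 0).
    """
    if end is None:
        end = sample.sequence_length
    n_windows = int(np.floor((end - start) / window_bp))
    edges = start + np.arange(n_windows + 1) * window_bp
    idx = np.searchsorted(sample.positions, edges)
    windows = []
    for w in range(n_windows):
        lo, hi = idx[w], idx[w + 1]
        windows.append(HaplotypeWindow(
            matrix=sample.matrix[:, lo:hi],
            positions=sample.positions[lo:hi],
            interval=(float(edges[w]), float(edges[w + 1])),
            polarized=sample.polarized,
        ))
    return windows


def ksk_stat(K_list, S_list) -> float:
    """Mean of (K_i - S_i) / K_i^2 over windows; the ksk(n)^2 statistic."""
    K = np.asarray(K_list, dtype=float)
    S = np.asarray(S_list, dtype=float)
    if K.size != S.size or K.size == 0:
        raise ValueError("K and S lists must be non-empty and equal length")
    if np.any(K < 1):
        raise ValueError("invalid window: K must be >= 1")
    return float(np.mean((K - S) / K**2))


@dataclass
class KskProfile:
    """Per-position ksk(n)^2 values along a chromosome.

    ``positions`` are midpoints of each n-window set; ``spans`` the (start,
    end) of the set; ``significant`` is filled by thresholding steps.
    """

    positions: np.ndarray
    values: np.ndarray
    n_windows: int
    window_bp: float
    chrom: str | None = None
    spans: np.ndarray | None = None
    significant: np.ndarray | None = None

    def __len__(self) -> int:
        return self.values.size

    @property
    def min_value(self) -> float:
        return float(self.values.min()) if self.values.size else np.nan


def sliding_ksk(stats_list: list[WindowStats], n: int = 20,
                chrom: str | None = None) -> KskProfile:
    """Sliding ksk(n)^2 over contiguous, fixed-width windows (stride 1 window).

    Each value is placed at the midpoint of its n-window set.  Windows with
    S = 0 contribute (K - S)/K^2 = 1 (K = 1), keeping the statistic defined
    genome-wide.
    """
    m = len(stats_list)
    if m == 0:
        raise ValueError("no windows")
    window_bp = stats_list[0].interval[1] - stats_list[0].interval[0]
    if m < n:
        return KskProfile(np.empty(0), np.empty(0), n, window_bp, chrom,
                          spans=np.empty((0, 2)))
    K = np.array([ws.K for ws in stats_list], dtype=float)
    S = np.array([ws.S for ws in stats_list], dtype=float)
    per = (K - S) / K**2
    csum = np.concatenate([[0.0], np.cumsum(per)])
    values = (csum[n:] - csum[:-n]) / n
    starts = np.array([ws.interval[0] for ws in stats_list])
    ends = np.array([ws.interval[1] for ws in stats_list])
    spans = np.column_stack([starts[: m - n + 1], ends[n - 1:]])
    midpoints = spans.mean(axis=1)
    return KskProfile(midpoints, values, n, window_bp, chrom, spans=spans)


def fine_scan(sample: HaplotypeSample, window_bp: float = 10_000,
              step_bp: float = 1_000, start: float = 0.0,
              end: float | None = None, chrom: str | None = None) -> KskProfile:
    """ksk(1)^2 for overlapping windows at ``step_bp`` stride over a region."""
    if end is None:
        end = sample.sequence_length
    region_len = end - start
    if region_len < window_bp:
        raise ValueError("region shorter than the window")
    n_vals = int(np.floor((region_len - window_bp) / step_bp)) + 1
    starts = start + np.arange(n_vals) * step_bp
    lo = np.searchsorted(sample.positions, starts)
    hi = np.searchsorted(sample.positions, starts + window_bp)
    values = np.empty(n_vals)
    for i in range(n_vals):
        sub = sample.matrix[:, lo[i]:hi[i]]
        counts = sub.sum(axis=0)
        seg = (counts > 0) & (counts < sample.num_chromosomes)
        S = int(seg.sum())
        K = int(haplotype_counts(sub[:, seg]).size) if S else 1
        values[i] = (K - S) / K**2
    spans = np.column_stack([starts, starts + window_bp])
    return KskProfile(spans.mean(axis=1), values, 1, window_bp, chrom, spans=spans)


def pairwise_diff_matrix(win: HaplotypeWindow) -> tuple[np.ndarray, np.ndarray]:
    """Hamming distances between the distinct haplotypes of a window.

    Returns ``(dist, counts)``: a symmetric K x K matrix of pairwise
    differences between distinct haplotypes and the multiplicity of each
    (counts sum to n).  Supports haplotype-network views of a window.
    """
    if win.matrix.shape[1] == 0:
        return np.zeros((1, 1), dtype=int), np.array([win.n])
    uniq, counts = np.unique(np.ascontiguousarray(win.matrix), axis=0,
                             return_counts=True)
    diff = (uniq[:, None, :] != uniq[None, :, :]).sum(axis=2)
    return diff.astype(int), counts


def stats_table(stats_list: list[WindowStats], chrom: str = "1"):
    """Tabular (BED-compatible) per-window statistics as a pandas DataFrame."""
    import pandas as pd

    rows = [{
        "chrom": chrom,
        "start": int(ws.interval[0]),
        "end": int(ws.interval[1]),
        "midpoint": ws.midpoint,
        "S": ws.S, "pi": ws.pi, "D": ws.D, "H_FW": ws.H_FW, "E": ws.E,
        "K": ws.K, "H": ws.H, "M": ws.M,
        "ksk1": (ws.K - ws.S) / ws.K**2,
    } for ws in stats_list]
    return pd.DataFrame(rows)
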