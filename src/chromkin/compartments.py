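"""A/B compartment calling on contact matrices and switch analysis.

The pipeline follows the standard eigenvector method: mask low-coverage
bins, divide each diagonal by its mean (observed/expected), take the Pearson
correlation matrix, and call compartments from the sign of its first
principal component, oriented so euchromatin-labelled reference bins carry
positive PC1.  Switches between two conditions are sign changes of PC1
passing a compartment-strength threshold (default 0.01), and their
enrichment near compartment boundaries is assessed with a permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .genome_io import CompartmentTrack
from .state import E


@dataclass
class ContactMatrix:
    """Square, symmetric, nonnegative contact-frequency matrix."""

    matrix: np.ndarray
    bin_size: int = 40_000
    chrom: str = "unknown"
    balanced: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T, rtol=1e-6, atol=1e-8):
            raise ValueError("contact matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("contact matrix must be nonnegative")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def balance_matrix(cm: ContactMatrix, tol: float = 1e-5, max_iter: int = 200) -> ContactMatrix:
    """Iterative correction to (approximately) equal row sums.

    Plain alternating row/column normalization on the unmasked submatrix;
    zero-coverage rows are left untouched.
    """
    m = cm.matrix.copy()
    live = m.sum(axis=1) > 0
    sub = m[np.ix_(live, live)]
    for _ in range(max_iter):
        rs = sub.sum(axis=1)
        rs /= rs.mean()
        sub /= np.outer(np.sqrt(rs), np.sqrt(rs))
        if np.abs(sub.sum(axis=1) / sub.sum(axis=1).mean() - 1.0).max() < tol:
            break
    m[np.ix_(live, live)] = sub
    return ContactMatrix(matrix=m, bin_size=cm.bin_size, chrom=cm.chrom, balanced=True)


@dataclass
class CompartmentCall:
    """Per-bin PC1 with A/B labels (A means oriented PC1 > 0)."""

    pc1: np.ndarray
    mask: np.ndarray  # True = usable bin
    bin_size: int
    oriented: bool
    eigengap_warning: bool = False

    @property
    def labels(self) -> np.ndarray:
        """'A', 'B' or 'masked' per bin."""
        out = np.full(self.pc1.size, "masked", dtype=object)
        out[self.mask & (self.pc1 > 0)] = "A"
        out[self.mask & (self.pc1 <= 0)] = "B"
        return out.astype(str)

    def boundaries(self) -> np.ndarray:
        """Indices i such that PC1 changes sign between unmasked bins i, i+1."""
        idx = np.flatnonzero(self.mask)
        s = np.sign(self.pc1[idx])
        change = np.flatnonzero(s[:-1] * s[1:] < 0)
        return idx[change]


def compartment_pc1(
    cm: ContactMatrix,
    orientation_track: CompartmentTrack | None = None,
    mask_fraction_of_median: float = 0.1,
) -> CompartmentCall:
    """Observed/expected -> Pearson correlation -> first PC -> A/B call.

    Bins whose row sum falls below ``mask_fraction_of_median`` times the
    median row sum are masked out before the correlation step.  With an
    orientation track the PC1 sign is fixed so that E-labelled bins have
    positive mean PC1; otherwise the sign is arbitrary and flagged.
    """
    m = cm.matrix
    n = cm.n_bins
    if n < 20:
        raise ValueError("need at least 20 bins for a compartment call")
    rowsum = m.sum(axis=1)
    mask = rowsum > mask_fraction_of_median * np.median(rowsum)
    sub = m[np.ix_(mask, mask)]
    k = sub.shape[0]
    if k < 20:
        raise ValueError("fewer than 20 unmasked bins")

    # observed / expected by diagonal mean (with pseudocount for empty bands)
    oe = np.empty_like(sub)
    for d in range(k):
        band = np.diagonal(sub, offset=d)
        mean = band.mean()
        vals = band / (mean if mean > 0 else 1.0)
        idx = np.arange(k - d)
        oe[idx, idx + d] = vals
        oe[idx + d, idx] = vals

    sd = oe.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("degenerate matrix: constant row in observed/expected")
    corr = np.corrcoef(oe)
    pca = PCA(n_components=2)
    comp = pca.fit_transform(corr)
    pc1_sub = comp[:, 0]
    var = pca.explained_variance_
    eigengap_warning = bool(var[0] - var[1] < 0.05 * var[0])

    pc1 = np.zeros(n)
    pc1[mask] = pc1_sub
    # normalize scale so thresholds are comparable across matrices
    amax = np.abs(pc1_sub).max()
    if amax > 0:
        pc1 /= amax

    oriented = False
    if orientation_track is not None:
        if orientation_track.n_beads != n:
            raise ValueError("orientation track length mismatch")
        e_bins = (orientation_track.marks == E) & mask
        if e_bins.any() and pc1[e_bins].mean() < 0:
            pc1 = -pc1
        oriented = True
    return CompartmentCall(
        pc1=pc1, mask=mask, bin_size=cm.bin_size, oriented=oriented,
        eigengap_warning=eigengap_warning,
    )


@dataclass
class SwitchSet:
    """Bins that changed compartment between two conditions."""

    b_to_a: np.ndarray
    a_to_b: np.ndarray
    strength_threshold: float
    weak_origin_fraction: float = np.nan

    @property
    def all_switches(self) -> np.ndarray:
        return np.sort(np.concatenate([self.b_to_a, self.a_to_b]))


def detect_switches(
    call_control: CompartmentCall,
    call_treated: CompartmentCall,
    strength_threshold: float = 0.01,
) -> SwitchSet:
    """Sign changes of PC1 passing the treated-condition strength threshold.

    B->A: control PC1 < 0 and treated PC1 > +threshold; A->B: control > 0
    and treated < -threshold.  Also reports the fraction of switching bins
    whose control |PC1| was 0.1 or less (weakly committed origins).
    """
    if call_control.pc1.size != call_treated.pc1.size:
        raise ValueError("bin count mismatch between conditions")
    ok = call_control.mask & call_treated.mask
    c = call_control.pc1
    t = call_treated.pc1
    b_to_a = np.flatnonzero(ok & (c < 0) & (t > strength_threshold))
    a_to_b = np.flatnonzero(ok & (c > 0) & (t < -strength_threshold))
    switches = np.concatenate([b_to_a, a_to_b])
    weak = float((np.abs(c[switches]) <= 0.1).mean()) if switches.size else np.nan
    return SwitchSet(
        b_to_a=b_to_a, a_to_b=a_to_b,
        strength_threshold=strength_threshold,
        weak_origin_fraction=weak,
    )


def switch_boundary_enrichment(
    switches: SwitchSet,
    call_control: CompartmentCall,
    window_bp: int = 40_000,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Fraction of switched bins within ``window_bp`` of a control-PC1 sign
    boundary, with a one-sided permutation null of equal-size random bin
    sets drawn from the unmasked bins."""
    bounds = call_control.boundaries()
    if bounds.size == 0:
        raise ValueError("control call has no compartment boundaries")
    sw = switches.all_switches
    if sw.size == 0:
        return {"fraction_within_window": 0.0, "p_value": 1.0,
                "note": "no switches", "window_bp": window_bp}
    win_bins = window_bp // call_control.bin_size

    def frac_near(bins: np.ndarray) -> float:
        # boundary index b sits between bins b and b+1
        d = np.min(
            np.abs(bins[:, None] - bounds[None, :] - 0.5) - 0.5,
            axis=1,
        )
        return float((np.maximum(d, 0) <= win_bins).mean())

    obs = frac_near(sw)
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(call_control.mask)
    null = np.empty(n_permutations)
    for p in range(n_permutations):
        null[p] = frac_near(rng.choice(pool, size=sw.size, replace=False))
    p_val = float((np.sum(null >= obs) + 1) / (n_permutations + 1))
    return {
        "fraction_within_window": obs,
        "null_mean": float(null.mean()),
        "p_value": p_val,
        "window_bp": window_bp,
        "n_switches": int(sw.size),
    }


def read_dense_matrix(path, bin_size: int = 40_000, chrom: str = "unknown") -> ContactMatrix:
    """Dense whitespace/tab-separated text matrix."""
    m = np.loadtxt(path)
    return ContactMatrix(matrix=m, bin_size=bin_size, chrom=chrom)


def write_dense_matrix(cm: ContactMatrix, path) -> None:
    np.savetxt(path, cm.matrix, fmt="%.6g", delimiter="\t")
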