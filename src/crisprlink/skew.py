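"""Nucleotide skews and replication-origin selection.

In many prokaryotes the leading strand is G-rich, so the cumulative GC skew
(G-C)/(G+C) traced along the chromosome falls on one replichore and rises
on the other: its minimum marks the replication origin and its maximum the
terminus.  The AT, purine-pyrimidine (R-Y) and amino-keto (M-K) skews are
weaker but corroborating tracks.  Sign convention here: skew positive when
G (resp. A, R, M) is in excess, origin at the cumulative GC minimum, so the
leading strand is G-rich downstream of the origin.

The origin picker takes the global cumulative minimum; a candidate lister
exposes the deepest local minima for manual review of genomes where the
global minimum is not the biologically sensible choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Contig


@dataclass
class SkewProfile:
    """Windowed and cumulative skew tracks for one contig."""

    contig_id: str
    window: int
    step: int
    starts: np.ndarray          # window start positions (0-based)
    ends: np.ndarray            # window end positions (exclusive)
    gc: np.ndarray
    at: np.ndarray
    ry: np.ndarray
    mk: np.ndarray
    cum_gc: np.ndarray = field(init=False)
    cum_at: np.ndarray = field(init=False)
    cum_ry: np.ndarray = field(init=False)
    cum_mk: np.ndarray = field(init=False)
    origin_index: int | None = None   # nt position once selected
    corroboration: dict[str, bool] | None = None

    def __post_init__(self) -> None:
        self.cum_gc = np.cumsum(self.gc)
        self.cum_at = np.cumsum(self.at)
        self.cum_ry = np.cumsum(self.ry)
        self.cum_mk = np.cumsum(self.mk)

    @property
    def n_windows(self) -> int:
        return len(self.starts)


_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}  # N excluded from all counts


def windowed_skews(contig: Contig, window: int = 1000, step: int | None = None) -> SkewProfile:
    """Per-window GC/AT/RY/MK skews plus their cumulative tracks.

    A trailing partial window is kept when it covers at least half the
    window length.  A window with a zero denominator (e.g. no G or C at
    all) gets skew 0.
    """
    step = step or window
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    n = contig.length
    if window > n:
        raise ValueError(f"window {window} exceeds contig length {n}")

    codes = np.frombuffer(contig.seq.encode("ascii"), dtype=np.uint8)
    # prefix sums of per-base counts; N contributes to none of them
    prefix = np.zeros((4, n + 1), dtype=np.int64)
    for base, idx in _CODES.items():
        np.cumsum(codes == ord(base), out=prefix[idx, 1:])

    starts_all = np.arange(0, n, step)
    ends_all = np.minimum(starts_all + window, n)
    keep = (ends_all - starts_all >= window) | (ends_all - starts_all >= window / 2)
    starts, ends = starts_all[keep], ends_all[keep]

    a, c, g, t = (prefix[i, ends] - prefix[i, starts] for i in range(4))

    def _ratio(num, den):
        return np.divide(num, den, out=np.zeros(len(starts), dtype=float), where=den > 0)

    total = a + c + g + t
    return SkewProfile(
        contig_id=contig.id,
        window=window,
        step=step,
        starts=starts,
        ends=ends,
        gc=_ratio(g - c, g + c),
        at=_ratio(a - t, a + t),
        ry=_ratio((a + g) - (c + t), total),
        mk=_ratio((a + c) - (g + t), total),
    )


def find_origin(profile: SkewProfile) -> int:
    """Replication-origin position: the boundary after the window where the
    cumulative GC skew attains its global minimum (ties -> leftmost).

    Also sets advisory corroboration flags: whether the cumulative AT, R-Y
    and M-K tracks sit below their medians at that window.  The flags never
    veto the GC-based choice.
    """
    if profile.n_windows < 3:
        raise ValueError("need at least 3 windows to pick an origin")
    i = int(np.argmin(profile.cum_gc))
    origin = int(profile.ends[i])
    profile.origin_index = origin
    profile.corroboration = {
        name: bool(track[i] < np.median(track))
        for name, track in (
            ("at", profile.cum_at),
            ("ry", profile.cum_ry),
            ("mk", profile.cum_mk),
        )
    }
    return origin


def origin_candidates(profile: SkewProfile, n: int = 3) -> list[int]:
    """The n deepest local minima of the cumulative GC skew (nt positions),
    for manual review; the global minimum is always first."""
    c = profile.cum_gc
    k = len(c)
    is_min = np.ones(k, dtype=bool)
    is_min[1:] &= c[1:] < c[:-1]
    is_min[:-1] &= c[:-1] <= c[1:]
    idx = np.nonzero(is_min)[0]
    order = idx[np.argsort(c[idx], kind="stable")]
    return [int(profile.ends[i]) for i in order[:n]]


def rotate_to_origin(contig: Contig, origin: int) -> Contig:
    """Permute a circular contig so the base at ``origin`` becomes base +1."""
    if contig.topology != "circular":
        raise ValueError(f"contig {contig.id!r} is not circular; refusing to rotate")
    if not (0 <= origin < contig.length):
        raise ValueError(f"origin {origin} outside contig of length {contig.length}")
    return Contig(
        id=contig.id,
        seq=contig.seq[origin:] + contig.seq[:origin],
        description=contig.description,
        mean_depth=contig.mean_depth,
        topology="circular",
    )


def skew_table(profile: SkewProfile):
    """Long-form table of the per-window and cumulative tracks."""
    import pandas as pd

    return pd.DataFrame(
        {
            "window_start": profile.starts,
            "window_end": profile.ends,
            "gc_skew": profile.gc,
            "at_skew": profile.at,
            "ry_skew": profile.ry,
            "mk_skew": profile.mk,
            "cum_gc_skew": profile.cum_gc,
            "cum_at_skew": profile.cum_at,
            "cum_ry_skew": profile.cum_ry,
            "cum_mk_skew": profile.cum_mk,
        }
    )
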