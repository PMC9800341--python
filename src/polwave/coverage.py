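"""In-memory genome coverage track.

A :class:`CoverageTrack` stores, per chromosome, a set of sorted
non-overlapping half-open intervals with a float value each — the natural
in-memory form of a bedGraph.  Values are per-base coverage depth; the track
total (``sum(value * length)``) is the library depth used for rpm
normalization throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import FormatError

__all__ = ["CoverageTrack"]


@dataclass
class CoverageTrack:
    """Sparse per-base coverage over a genome.

    ``data`` maps chromosome name to ``(starts, ends, values)`` arrays of
    equal length, sorted by start, with non-overlapping intervals.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @classmethod
    def from_dense(cls, dense: dict[str, np.ndarray], bin_size: int) -> "CoverageTrack":
        """Build a track from per-bin dense arrays (one value per bin_size bp)."""
        data = {}
        for chrom, values in dense.items():
            n = len(values)
            starts = np.arange(n, dtype=np.int64) * bin_size
            ends = starts + bin_size
            data[chrom] = (starts, ends, np.asarray(values, dtype=float))
        return cls(data)

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def total(self) -> float:
        """Library depth: sum of value x interval length over the genome."""
        tot = 0.0
        for starts, ends, values in self.data.values():
            tot += float(np.sum((ends - starts) * values))
        return tot

    def scale(self, factor: float) -> "CoverageTrack":
        """Return a copy with all values multiplied by ``factor``."""
        return CoverageTrack(
            {
                c: (s.copy(), e.copy(), v * factor)
                for c, (s, e, v) in self.data.items()
            }
        )

    def add(self, other: "CoverageTrack") -> "CoverageTrack":
        """Sum two tracks (used to merge strand-specific coverage)."""
        out = {}
        for chrom in set(self.data) | set(other.data):
            pieces = [t.data[chrom] for t in (self, other) if chrom in t.data]
            if len(pieces) == 1:
                s, e, v = pieces[0]
                out[chrom] = (s.copy(), e.copy(), v.copy())
                continue
            # rasterize onto the union breakpoint grid
            bounds = np.unique(
                np.concatenate([p[0] for p in pieces] + [p[1] for p in pieces])
            )
            vals = np.zeros(len(bounds) - 1)
            mids = (bounds[:-1] + bounds[1:]) / 2.0
            for s, e, v in pieces:
                idx = np.searchsorted(s, mids, side="right") - 1
                ok = (idx >= 0) & (mids < e[np.clip(idx, 0, len(e) - 1)])
                vals[ok] += v[idx[ok]]
            out[chrom] = (bounds[:-1], bounds[1:], vals)
        return CoverageTrack(out)

    def total_count(self) -> float:
        """Sum of interval values, reading each value as a count per interval."""
        return float(sum(np.sum(v) for _, _, v in self.data.values()))

    def window_count(self, chrom: str, start: int, end: int) -> float:
        """Count in ``[start, end)``, distributing each interval's value
        uniformly over its bases (count-per-interval semantics)."""
        if chrom not in self.data:
            return 0.0
        starts, ends, values = self.data[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        frac = (e - s) / (ends[lo:hi] - starts[lo:hi])
        return float(np.sum(frac * values[lo:hi]))

    def binned_counts(self, chrom: str, chrom_size: int, bin_size: int) -> np.ndarray:
        """Per-bin counts over ``[0, chrom_size)`` (count-per-interval
        semantics; fractional overlap split proportionally)."""
        n_bins = int(np.ceil(chrom_size / bin_size))
        out = np.zeros(n_bins)
        if chrom not in self.data:
            return out
        starts, ends, values = self.data[chrom]
        for s, e, v in zip(starts, ends, values):
            s0 = max(int(s), 0)
            e0 = min(int(e), chrom_size)
            if e0 <= s0 or v == 0.0:
                continue
            per_base = v / (e - s)
            b0, b1 = s0 // bin_size, (e0 - 1) // bin_size
            if b0 == b1:
                out[b0] += (e0 - s0) * per_base
            else:
                out[b0] += ((b0 + 1) * bin_size - s0) * per_base
                out[b1] += (e0 - b1 * bin_size) * per_base
                if b1 - b0 > 1:
                    out[b0 + 1 : b1] += bin_size * per_base
        return out

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Total per-base coverage in ``[start, end)`` (0 outside the track)."""
        if chrom not in self.data:
            return 0.0
        starts, ends, values = self.data[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * values[lo:hi]))

    def binned(self, chrom: str, chrom_size: int, bin_size: int) -> np.ndarray:
        """Per-bin *sum* of per-base coverage over ``[0, chrom_size)``.

        The last bin may be shorter than ``bin_size``.
        """
        n_bins = int(np.ceil(chrom_size / bin_size))
        out = np.zeros(n_bins)
        if chrom not in self.data:
            return out
        starts, ends, values = self.data[chrom]
        for s, e, v in zip(starts, ends, values):
            s = max(int(s), 0)
            e = min(int(e), chrom_size)
            if e <= s or v == 0.0:
                continue
            b0, b1 = s // bin_size, (e - 1) // bin_size
            if b0 == b1:
                out[b0] += (e - s) * v
            else:
                out[b0] += ((b0 + 1) * bin_size - s) * v
                out[b1] += (e - b1 * bin_size) * v
                if b1 - b0 > 1:
                    out[b0 + 1 : b1] += bin_size * v
        return out

    def window_means(
        self, chrom: str, start: int, end: int, bin_size: int
    ) -> np.ndarray:
        """Mean per-base coverage in consecutive bins tiling ``[start, end)``.

        ``end - start`` must be a multiple of ``bin_size``.
        """
        width = end - start
        if width % bin_size:
            raise ValueError("window length must be a multiple of bin_size")
        n_bins = width // bin_size
        out = np.zeros(n_bins)
        if chrom not in self.data:
            return out
        starts, ends, values = self.data[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            s = max(int(s), start)
            e = min(int(e), end)
            if e <= s or v == 0.0:
                continue
            b0 = (s - start) // bin_size
            b1 = (e - start - 1) // bin_size
            if b0 == b1:
                out[b0] += (e - s) * v
            else:
                out[b0] += ((b0 + 1) * bin_size + start - s) * v
                out[b1] += (e - start - b1 * bin_size) * v
                if b1 - b0 > 1:
                    out[b0 + 1 : b1] += bin_size * v
        return out / bin_size

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_bedgraph(cls, path) -> "CoverageTrack":
        chroms: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise FormatError(f"{path}:{i}: expected 4 bedGraph fields")
                try:
                    start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
                except ValueError as exc:
                    raise FormatError(f"{path}:{i}: {exc}") from exc
                chroms.setdefault(parts[0], []).append((start, end, value))
        data = {}
        for chrom, rows in chroms.items():
            rows.sort()
            arr = np.asarray(rows, dtype=float)
            data[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        return cls(data)

    def to_bedgraph(self, path, omit_zero: bool = True) -> None:
        """Write the track; float values use repr-stable %.6g formatting."""
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                starts, ends, values = self.data[chrom]
                for s, e, v in zip(starts, ends, values):
                    if omit_zero and v == 0.0:
                        continue
                    fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")
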