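"""Domain types for variant calls, territories, coverage and panels of normals.

Coordinate conventions: ``VariantCall.pos`` is 1-based (VCF); territories and
coverage intervals are 0-based half-open (BED). Conversions happen only at I/O
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

VARIANT_CLASSES = frozenset(
    {"snv", "indel", "frameshift", "start_stop", "splice", "synonymous", "other"}
)
TRUTH_LABELS = frozenset({"somatic", "germline", "artifact"})

#: tolerance for the vaf == alt_depth/total_depth invariant (rounded inputs)
VAF_TOL = 5e-3


class ValidationError(ValueError):
    """An input value violates a documented invariant or precondition."""


class ContractError(RuntimeError):
    """Caller broke an API contract (mismatched inputs, missing verdicts...)."""


@dataclass(slots=True)
class VariantCall:
    """One called variant (single alternate allele) with its support evidence.

    ``vaf`` is the alternate allelic fraction (the Af of tumor-only / paired
    filtering); ``mq_pass_fraction`` is the fraction of reads at the locus with
    mapping quality > 1. ``population_maf`` is the germline-resource minor
    allele fraction and is ``None`` when the variant is unseen in the resource.
    ``truth_label`` carries simulator provenance only.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    vaf: float
    alt_fwd: int
    alt_rev: int
    mq_pass_fraction: float
    variant_class: str
    splice_offset: Optional[int] = None
    population_maf: Optional[float] = None
    in_dbsnp: bool = False
    in_cosmic: bool = False
    truth_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(
                f"unknown variant class {self.variant_class!r} at "
                f"{self.chrom}:{self.pos}"
            )
        if self.truth_label is not None and self.truth_label not in TRUTH_LABELS:
            raise ValidationError(f"unknown truth label {self.truth_label!r}")
        if self.alt_depth > self.total_depth:
            raise ValidationError(
                f"alt_depth {self.alt_depth} > total_depth {self.total_depth} at "
                f"{self.chrom}:{self.pos}"
            )
        if self.alt_fwd + self.alt_rev != self.alt_depth:
            raise ValidationError(
                f"strand counts {self.alt_fwd}+{self.alt_rev} != alt_depth "
                f"{self.alt_depth} at {self.chrom}:{self.pos}"
            )
        if self.total_depth > 0 and abs(self.vaf - self.alt_depth / self.total_depth) > VAF_TOL:
            raise ValidationError(
                f"vaf {self.vaf} inconsistent with {self.alt_depth}/{self.total_depth} "
                f"at {self.chrom}:{self.pos}"
            )
        if not (0.0 <= self.mq_pass_fraction <= 1.0):
            raise ValidationError("mq_pass_fraction outside [0,1]")
        if self.population_maf is not None and not (0.0 <= self.population_maf <= 1.0):
            raise ValidationError(
                f"population_maf {self.population_maf} outside [0,1]"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class SampleCallset:
    """All calls for one sample under one assay, with calling-mode provenance."""

    sample_id: str
    assay_id: str
    mode: str  # "tumor_only" | "paired"
    calls: list[VariantCall]
    matched_normal_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("tumor_only", "paired"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "paired" and self.matched_normal_id is None:
            raise ValidationError("paired mode requires matched_normal_id")
        self.calls = sorted(self.calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
        keys = [c.key for c in self.calls]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (chrom,pos,ref,alt) keys in callset")

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)


def _merge_intervals(
    intervals: Iterable[tuple[str, int, int]],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sort and merge overlapping/adjacent half-open intervals per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if start >= end:
            raise ValidationError(f"empty or inverted interval {chrom}:{start}-{end}")
        if start < 0:
            raise ValidationError(f"negative interval start {chrom}:{start}")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:  # overlap or abutment
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        starts = np.array([s for s, _ in out], dtype=np.int64)
        ends = np.array([e for _, e in out], dtype=np.int64)
        merged[chrom] = (starts, ends)
    return merged


@dataclass
class Territory:
    """A named set of genomic intervals (0-based half-open), e.g. a panel's
    coding space. Intervals are merged and sorted at construction."""

    name: str
    _by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, name: str, intervals: Iterable[tuple[str, int, int]]
    ) -> "Territory":
        return cls(name=name, _by_chrom=_merge_intervals(intervals))

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom, (starts, ends) in self._by_chrom.items():
            out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
        return out

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        starts, ends = self._by_chrom.get(chrom, (np.empty(0, np.int64),) * 2)
        return starts, ends

    @property
    def total_bases(self) -> int:
        return int(
            sum((ends - starts).sum() for starts, ends in self._by_chrom.values())
        )

    @property
    def coding_mb(self) -> float:
        return self.total_bases / 1e6

    def contains(self, chrom: str, pos0: int) -> bool:
        starts, ends = self.arrays(chrom)
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < ends[i]

    def contains_many(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        starts, ends = self.arrays(chrom)
        if starts.size == 0:
            return np.zeros(len(pos0), dtype=bool)
        i = np.searchsorted(starts, pos0, side="right") - 1
        ok = i >= 0
        res = np.zeros(len(pos0), dtype=bool)
        res[ok] = pos0[ok] < ends[i[ok]]
        return res

    def clip(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        """Intersect one interval with the territory; returns clipped pieces."""
        starts, ends = self.arrays(chrom)
        if starts.size == 0 or start >= end:
            return []
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        pieces = []
        for j in range(lo, hi):
            s = max(start, int(starts[j]))
            e = min(end, int(ends[j]))
            if s < e:
                pieces.append((s, e))
        return pieces


@dataclass
class CoverageProfile:
    """Per-base read depth over a territory, interval-encoded.

    Depth is defined only inside the territory: queries outside raise
    ``ValidationError``. Territory bases with no covering interval have
    depth 0 (explicitly, never by silent zero-fill outside the territory).
    """

    sample_id: str
    territory: Territory
    _by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @classmethod
    def from_intervals(
        cls,
        sample_id: str,
        territory: Territory,
        intervals: Iterable[tuple[str, int, int, int]],
        preclipped: bool = False,
    ) -> "CoverageProfile":
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, start, end, depth in intervals:
            if depth < 0:
                raise ValidationError(
                    f"negative depth {depth} at {chrom}:{start}-{end}"
                )
            if preclipped:
                by_chrom.setdefault(chrom, []).append((int(start), int(end), int(depth)))
            else:
                for s, e in territory.clip(chrom, int(start), int(end)):
                    by_chrom.setdefault(chrom, []).append((s, e, int(depth)))
        arrays = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            depths = np.array([d for _, _, d in ivs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping coverage intervals on {chrom}")
            arrays[chrom] = (starts, ends, depths)
        return cls(sample_id=sample_id, territory=territory, _by_chrom=arrays)

    @classmethod
    def from_arrays(
        cls,
        sample_id: str,
        territory: Territory,
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> "CoverageProfile":
        """Fast constructor for already-sorted, territory-aligned intervals."""
        return cls(sample_id=sample_id, territory=territory, _by_chrom=by_chrom)

    def intervals(self) -> Iterator[tuple[str, int, int, int]]:
        for chrom, (starts, ends, depths) in self._by_chrom.items():
            for s, e, d in zip(starts, ends, depths):
                yield chrom, int(s), int(e), int(d)

    def depth_at(self, chrom: str, pos0: int) -> int:
        if not self.territory.contains(chrom, pos0):
            raise ValidationError(
                f"position {chrom}:{pos0} outside territory {self.territory.name!r}"
            )
        starts, ends, depths = self._by_chrom.get(
            chrom, (np.empty(0, np.int64),) * 3
        )
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        if i >= 0 and pos0 < ends[i]:
            return int(depths[i])
        return 0

    def depths_at(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorized depth lookup; positions must lie inside the territory."""
        if len(pos0) and not bool(self.territory.contains_many(chrom, pos0).all()):
            raise ValidationError(
                f"positions outside territory {self.territory.name!r} on {chrom}"
            )
        starts, ends, depths = self._by_chrom.get(
            chrom, (np.empty(0, np.int64),) * 3
        )
        out = np.zeros(len(pos0), dtype=np.int64)
        if starts.size == 0:
            return out
        i = np.searchsorted(starts, pos0, side="right") - 1
        ok = (i >= 0) & (pos0 < ends[np.clip(i, 0, None)])
        out[ok] = depths[i[ok]]
        return out

    def callable_bases(
        self, min_coverage: int, territory: Optional[Territory] = None
    ) -> int:
        """Number of bases with depth strictly greater than ``min_coverage``."""
        if territory is None or territory is self.territory:
            total = 0
            for starts, ends, depths in self._by_chrom.values():
                sel = depths > min_coverage
                total += int((ends[sel] - starts[sel]).sum())
            return total
        total = 0
        for chrom, (starts, ends, depths) in self._by_chrom.items():
            sel = np.nonzero(depths > min_coverage)[0]
            for j in sel:
                for s, e in territory.clip(chrom, int(starts[j]), int(ends[j])):
                    total += e - s
        return total


@dataclass
class PanelOfNormals:
    """Allelic fractions of variants detected in a set of normal samples.

    ``entries`` maps (chrom, pos, ref, alt) to a list of (normal_id, Af_normal)
    for every normal in which the variant was detected; absence of a key means
    the variant was seen in no normal. Detection implies Af_normal > 0.
    """

    entries: dict[tuple[str, int, str, str], list[tuple[str, float]]]
    n_normals: int

    def __post_init__(self) -> None:
        for key, obs in self.entries.items():
            for normal_id, af in obs:
                if not (0.0 < af <= 1.0):
                    raise ValidationError(
                        f"Af_normal {af} for {key} in {normal_id} outside (0,1]"
                    )

    def afs_for(self, key: tuple[str, int, str, str]) -> list[tuple[str, float]]:
        return self.entries.get(key, [])

    def with_matched_normal(self, normal: SampleCallset) -> "PanelOfNormals":
        """Return a copy with the matched normal's allelic fractions merged in."""
        if len(normal) == 0:
            return self
        merged = {k: list(v) for k, v in self.entries.items()}
        for call in normal:
            if call.vaf <= 0:
                continue
            merged.setdefault(call.key, []).append((normal.sample_id, call.vaf))
        return PanelOfNormals(entries=merged, n_normals=self.n_normals + 1)
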