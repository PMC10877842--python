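"""Core in-memory containers shared across the package.

The central objects are :class:`VariantKey` (a biallelic SNV identity),
:class:`GenotypeMatrix` (samples x variants, alt-allele dosage coded 0/1/2),
:class:`AlleleFrequencyTable` (population x variant alt-allele frequencies,
the aggregate input to genotype simulation) and :class:`GenomicIntervalSet`
(BED-convention intervals).  All genomic positions follow the VCF convention
(1-based) except interval coordinates, which are BED 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

_ACGT = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one biallelic SNV.

    Only single-base substitutions are representable: ``ref`` and ``alt``
    are single uppercase bases and must differ.  ``build`` tags the genome
    build; matrices and models on different builds never mix silently.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    build: str = "GRCh38"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if len(allele) != 1 or allele not in _ACGT:
                raise ValidationError(
                    f"{name} must be a single uppercase ACGT base, got {allele!r}"
                )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of alt-allele dosages in {0, 1, 2}.

    Missing genotypes are coded 0 (conflated with homozygous reference by
    design -- the encoding the classifiers are trained on).  ``labels``
    optionally maps sample IDs to population labels.
    """

    variants: list[VariantKey]
    samples: list[str]
    values: np.ndarray
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.values.size and not np.isin(self.values, (0, 1, 2)).all():
            bad = np.unique(self.values[~np.isin(self.values, (0, 1, 2))])
            raise ValidationError(f"genotype values outside {{0,1,2}}: {bad}")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample IDs")
        if len(set(self.variants)) != len(self.variants):
            raise ValidationError("duplicate variant keys")
        if self.labels is not None:
            missing = [s for s in self.samples if s not in self.labels]
            if missing:
                raise ValidationError(f"labels missing for samples: {missing[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValidationError("matrix carries no population labels")
        return np.array([self.labels[s] for s in self.samples])

    def select_variants(self, mask_or_index) -> "GenotypeMatrix":
        """New matrix restricted to the given variant columns (mask or indices)."""
        idx = np.arange(self.n_variants)[mask_or_index]
        return replace(
            self,
            variants=[self.variants[i] for i in idx],
            values=self.values[:, idx],
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        keep = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in keep if s not in pos]
        if missing:
            raise ValidationError(f"unknown sample IDs: {missing[:5]}")
        idx = [pos[s] for s in keep]
        labels = {s: self.labels[s] for s in keep} if self.labels else None
        return GenotypeMatrix(
            variants=list(self.variants),
            samples=keep,
            values=self.values[idx, :],
            labels=labels,
        )


@dataclass
class GenomicIntervalSet:
    """BED-convention intervals: (chrom, start, end[, name]), 0-based half-open."""

    intervals: list[tuple]

    def __post_init__(self) -> None:
        for iv in self.intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            if start >= end:
                raise ValidationError(f"interval start >= end: {chrom}:{start}-{end}")

    def chroms(self) -> set[str]:
        return {iv[0] for iv in self.intervals}

    def merged(self) -> "GenomicIntervalSet":
        """Overlapping intervals merged per chromosome (book-ended stay apart).

        Merged composite names join member names with '+', mirroring the
        convention of collapsing overlapping genes into one region.
        """
        by_chrom: dict[str, list[tuple]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv[0], []).append(iv)
        out: list[tuple] = []
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom], key=lambda iv: (int(iv[1]), int(iv[2])))
            cur_start, cur_end = int(ivs[0][1]), int(ivs[0][2])
            cur_names = [ivs[0][3]] if len(ivs[0]) > 3 else []
            for iv in ivs[1:]:
                s, e = int(iv[1]), int(iv[2])
                name = iv[3] if len(iv) > 3 else None
                if s < cur_end:
                    cur_end = max(cur_end, e)
                    if name is not None and name not in cur_names:
                        cur_names.append(name)
                else:
                    out.append(_mk_interval(chrom, cur_start, cur_end, cur_names))
                    cur_start, cur_end = s, e
                    cur_names = [name] if name is not None else []
            out.append(_mk_interval(chrom, cur_start, cur_end, cur_names))
        return GenomicIntervalSet(out)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        p = pos_1based - 1
        return any(
            iv[0] == chrom and int(iv[1]) <= p < int(iv[2]) for iv in self.intervals
        )


def _mk_interval(chrom: str, start: int, end: int, names: list[str]) -> tuple:
    if names:
        return (chrom, start, end, "+".join(names))
    return (chrom, start, end)


@dataclass
class AlleleFrequencyTable:
    """Population x variant alt-allele frequencies with a missingness mask.

    ``freqs[p, v]`` is the alternate-allele frequency of variant ``v`` in
    population ``p``; a masked cell means no data was published for that
    (population, variant) pair -- which is *not* the same as frequency 0.
    """

    variants: list[VariantKey]
    populations: list[str]
    freqs: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        shape = (len(self.populations), len(self.variants))
        if self.freqs.shape != shape:
            raise ValidationError(
                f"freqs shape {self.freqs.shape} != populations x variants {shape}"
            )
        if self.missing is None:
            self.missing = np.isnan(self.freqs)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != shape:
                raise ValidationError("missing-mask shape mismatch")
        obs = self.freqs[~self.missing]
        if obs.size and ((obs < 0) | (obs > 1)).any():
            raise ValidationError("non-missing frequencies must lie in [0, 1]")
        if len(set(self.variants)) != len(self.variants):
            raise ValidationError("duplicate variant keys")
        if len(set(self.populations)) != len(self.populations):
            raise ValidationError("duplicate population labels")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def select_variants(self, mask_or_index) -> "AlleleFrequencyTable":
        idx = np.arange(self.n_variants)[mask_or_index]
        return AlleleFrequencyTable(
            variants=[self.variants[i] for i in idx],
            populations=list(self.populations),
            freqs=self.freqs[:, idx],
            missing=self.missing[:, idx],
        )
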