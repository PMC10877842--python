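"""Genotype simulation from aggregate allele frequencies.

Individual-level training cohorts are drawn from published population
allele frequencies: at a site with alt-allele frequency ``q`` a diploid
genotype is sampled from the Hardy-Weinberg proportions
((1-q)^2, 2q(1-q), q^2).  Variants are simulated independently — linkage
disequilibrium is deliberately not modelled, so simulated individuals are
"typical" members of a population rather than realistic haplotype mosaics.

For fully self-contained testing, :func:`generate_synthetic_world` builds
diverged-population AF tables under the Balding-Nichols model: each
population's frequency at a site is Beta-distributed around an ancestral
frequency ``p`` with variance ``F * p * (1 - p)``, where ``F`` acts as an
FST-like divergence knob.  Nested mode repeats the draw inside each
continental group with a second, smaller divergence, yielding a two-level
continental/subcontinental label hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    AlleleFrequencyTable,
    GenotypeMatrix,
    ValidationError,
    VariantKey,
)
from .io import BUILD_HEADER_KEY

RNG_ALGORITHM = "numpy PCG64 (default_rng)"


@dataclass
class SimulationConfig:
    """How many individuals to simulate per population, and with what seed."""

    n_per_population: int = 100
    seed: int = 0
    hwe: bool = True  # genotype model is Hardy-Weinberg; kept explicit

    def __post_init__(self) -> None:
        if self.n_per_population < 1:
            raise ValidationError("n_per_population must be >= 1")
        if not self.hwe:
            raise ValidationError("only the Hardy-Weinberg genotype model is supported")


@dataclass
class SyntheticWorldConfig:
    """Parameters of a Balding-Nichols synthetic world.

    ``divergence`` is the continental-level F; when ``n_subpopulations_per``
    is set, each continental group receives that many child populations
    drawn with ``sub_divergence``.
    """

    n_populations: int = 4
    n_variants: int = 1000
    divergence: float = 0.1
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0
    n_subpopulations_per: int | None = None
    sub_divergence: float = 0.02
    build: str = "synthetic"

    def __post_init__(self) -> None:
        if not (0.0 < self.divergence < 1.0):
            raise ValidationError("divergence must be in (0, 1)")
        if self.n_subpopulations_per is not None and not (
            0.0 < self.sub_divergence < 1.0
        ):
            raise ValidationError("sub_divergence must be in (0, 1)")
        if self.n_variants < 1 or self.n_populations < 2:
            raise ValidationError("need n_variants >= 1 and n_populations >= 2")
        lo, hi = self.ancestral_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValidationError("ancestral_range must satisfy 0 <= lo < hi <= 1")


def genotype_probabilities(q) -> tuple:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2).

    Accepts a scalar or array frequency in [0, 1]; returns the
    (ref, het, hom-alt) triple (stacked along the last axis for arrays).
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValidationError("allele frequency must lie in [0, 1]")
    p_ref = (1.0 - q) ** 2
    p_het = 2.0 * q * (1.0 - q)
    p_hom = q**2
    if q.ndim == 0:
        return (float(p_ref), float(p_het), float(p_hom))
    return np.stack([p_ref, p_het, p_hom], axis=-1)


def simulate_individuals(
    aft: AlleleFrequencyTable, config: SimulationConfig
) -> GenotypeMatrix:
    """Draw labelled individuals from an allele-frequency table.

    Each genotype is drawn independently from the Hardy-Weinberg
    proportions of its population's frequency; missing (population,
    variant) cells always emit genotype 0.  Deterministic given the seed:
    one PCG64 stream, consumed population-major.
    """
    if aft.n_variants == 0 or aft.n_populations == 0:
        raise ValidationError("allele-frequency table is empty")
    rng = np.random.default_rng(config.seed)
    n = config.n_per_population
    blocks: list[np.ndarray] = []
    samples: list[str] = []
    labels: dict[str, str] = {}
    for p_idx, pop in enumerate(aft.populations):
        q = np.where(aft.missing[p_idx], 0.0, aft.freqs[p_idx])
        # genotype = #alt alleles among two independent Bernoulli(q) draws
        u = rng.random((n, 2, aft.n_variants))
        geno = (u < q[None, None, :]).sum(axis=1).astype(np.int8)
        blocks.append(geno)
        for k in range(n):
            sid = f"{pop}_sim{k}"
            samples.append(sid)
            labels[sid] = pop
    return GenotypeMatrix(
        variants=list(aft.variants),
        samples=samples,
        values=np.concatenate(blocks, axis=0),
        labels=labels,
    )


def _balding_nichols_draw(
    rng: np.random.Generator, p: np.ndarray, F: float, n_pops: int
) -> np.ndarray:
    """Per-population frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F), one row per pop."""
    scale = (1.0 - F) / F
    a = np.clip(p * scale, 1e-12, None)
    b = np.clip((1.0 - p) * scale, 1e-12, None)
    return rng.beta(a[None, :], b[None, :], size=(n_pops, p.size))


def generate_synthetic_world(
    config: SyntheticWorldConfig,
) -> tuple[AlleleFrequencyTable, dict[str, str] | None]:
    """Build a diverged-population AF table (and hierarchy in nested mode).

    Returns ``(aft, hierarchy)`` where ``hierarchy`` maps subpopulation
    label -> continental label, or ``None`` in flat mode.  Populations are
    named ``pop1..popK`` (flat) or ``c<i>_s<j>`` with parents ``c<i>``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_range
    p = rng.uniform(lo, hi, size=config.n_variants)
    cont = _balding_nichols_draw(rng, p, config.divergence, config.n_populations)
    variants = [
        VariantKey("1", j + 1, "A", "G", config.build)
        for j in range(config.n_variants)
    ]
    if config.n_subpopulations_per is None:
        pops = [f"pop{i + 1}" for i in range(config.n_populations)]
        return (
            AlleleFrequencyTable(variants=variants, populations=pops, freqs=cont),
            None,
        )
    rows: list[np.ndarray] = []
    pops = []
    hierarchy: dict[str, str] = {}
    for i in range(config.n_populations):
        subs = _balding_nichols_draw(
            rng, cont[i], config.sub_divergence, config.n_subpopulations_per
        )
        for j in range(config.n_subpopulations_per):
            name = f"c{i + 1}_s{j + 1}"
            pops.append(name)
            hierarchy[name] = f"c{i + 1}"
            rows.append(subs[j])
    aft = AlleleFrequencyTable(
        variants=variants, populations=pops, freqs=np.stack(rows)
    )
    return aft, hierarchy


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_cohort_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write the cohort as a minimal VCF v4.2 (GT only).

    Round-trips exactly through :func:`snvancestry.io.read_vcf_genotypes`:
    dosage 1 becomes "0/1", dosage 2 becomes "1/1".
    """
    builds = {v.build for v in matrix.variants}
    build = builds.pop() if len(builds) == 1 else "unknown"
    # column order is preserved verbatim so read(write(M)) == M exactly;
    # callers wanting coordinate-sorted output should sort the matrix first
    order = range(matrix.n_variants)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##{BUILD_HEADER_KEY}={build}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(matrix.variants[i].chrom for i in order):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in order:
            v = matrix.variants[i]
            gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.values[:, i])
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n"
            )
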