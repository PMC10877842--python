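"""File I/O: VCF cohorts, BED intervals, allele-frequency tables, model bundles.

VCF parsing is delegated to cyvcf2; only biallelic SNVs are retained and
genotypes are collapsed to the alt-allele dosage encoding used throughout
(hom-alt = 2, het = 1, hom-ref / missing / half-call = 0).
"""

from __future__ import annotations

import logging
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AlleleFrequencyTable,
    GenomicIntervalSet,
    GenotypeMatrix,
    ValidationError,
    VariantKey,
    _ACGT,
)

logger = logging.getLogger(__name__)

BUILD_HEADER_KEY = "ancestry_build"
BUNDLE_FORMAT_VERSION = 1


class ModelBundleError(ValueError):
    """Raised when a model bundle cannot be loaded or is inconsistent."""


def read_vcf_genotypes(
    vcf_path,
    sample_subset: list[str] | None = None,
    build: str | None = None,
) -> GenotypeMatrix:
    """Read a VCF into the 0/1/2 dosage encoding.

    Biallelic SNVs only: multiallelic records and indels are dropped (with a
    logged count).  Diploid GT is required; records of other ploidy are
    skipped with a warning.  Missing calls and half-calls count as 0.
    ``build`` overrides the ``##ancestry_build=`` header tag when given.
    """
    from cyvcf2 import VCF

    path = str(vcf_path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise OSError(f"cannot read VCF {path!r}: {exc}") from exc

    header_build = _build_from_header(vcf.raw_header)
    build = build or header_build or "unknown"

    samples = list(vcf.samples)
    if not samples:
        raise ValidationError(f"{path}: VCF has no samples (GT field required)")
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in samples]
        if missing:
            raise ValidationError(f"{path}: samples not in VCF: {missing}")
        sample_idx = [samples.index(s) for s in sample_subset]
        samples = list(sample_subset)
    else:
        sample_idx = list(range(len(samples)))

    variants: list[VariantKey] = []
    columns: list[np.ndarray] = []
    n_multi = n_nonsnv = n_ploidy = 0
    for rec in vcf:
        if "GT" not in (rec.FORMAT or []):
            raise ValidationError(
                f"{path}: record {rec.CHROM}:{rec.POS} has no GT field"
            )
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _ACGT or alt not in _ACGT:
            n_nonsnv += 1
            continue
        gts = rec.genotypes  # [allele1, allele2, ..., phased] per sample
        col = np.zeros(len(sample_idx), dtype=np.int8)
        bad_ploidy = False
        for out_i, si in enumerate(sample_idx):
            g = gts[si]
            alleles = g[:-1]
            if len(alleles) != 2:
                bad_ploidy = True
                break
            a, b = alleles
            if a < 0 or b < 0:  # missing or half-call -> 0
                continue
            col[out_i] = int(a == 1) + int(b == 1)
        if bad_ploidy:
            n_ploidy += 1
            logger.warning(
                "skipping non-diploid record %s:%s", rec.CHROM, rec.POS
            )
            continue
        variants.append(VariantKey(rec.CHROM, rec.POS, ref, alt, build))
        columns.append(col)
    if n_multi or n_nonsnv or n_ploidy:
        logger.info(
            "%s: dropped %d multiallelic, %d non-SNV, %d non-diploid records",
            path, n_multi, n_nonsnv, n_ploidy,
        )
    values = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(variants=variants, samples=samples, values=values)


def _build_from_header(raw_header: str) -> str | None:
    for line in raw_header.splitlines():
        if line.startswith(f"##{BUILD_HEADER_KEY}="):
            return line.split("=", 1)[1].strip()
    return None


def intersect_matrix(
    matrix: GenotypeMatrix,
    regions: GenomicIntervalSet,
    normalize_chroms: bool = False,
) -> GenotypeMatrix:
    """Restrict matrix columns to variants inside the interval set.

    A variant at 1-based ``pos`` is kept when ``pos - 1`` lies in some
    half-open interval [start, end).  Chromosome names must match exactly
    unless ``normalize_chroms`` strips a leading "chr" from both sides; a
    detectable dialect mismatch (names matching only after stripping) is a
    hard error otherwise.
    """
    def norm(c: str) -> str:
        return c[3:] if c.lower().startswith("chr") else c

    region_chroms = regions.chroms()
    if normalize_chroms:
        key = norm
        region_names = {norm(c) for c in region_chroms}
    else:
        key = lambda c: c  # noqa: E731
        region_names = region_chroms
        mismatched = sorted(
            {
                v.chrom
                for v in matrix.variants
                if v.chrom not in region_chroms
                and norm(v.chrom) in {norm(c) for c in region_chroms}
            }
        )
        if mismatched:
            raise ValidationError(
                "chromosome naming dialect mismatch between matrix and regions "
                f"(e.g. {mismatched[:5]}); pass normalize_chroms=True to strip "
                "'chr' prefixes"
            )

    # sorted interval bounds per chromosome for a searchsorted lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    merged = regions.merged()
    for iv in merged.intervals:
        by_chrom.setdefault(key(iv[0]), ([], []))
    for iv in merged.intervals:
        starts, ends = by_chrom[key(iv[0])]
        starts.append(int(iv[1]))
        ends.append(int(iv[2]))
    by_chrom = {
        c: (np.asarray(s), np.asarray(e)) for c, (s, e) in by_chrom.items()
    }

    keep = np.zeros(matrix.n_variants, dtype=bool)
    for i, v in enumerate(matrix.variants):
        c = key(v.chrom)
        if c not in by_chrom:
            continue
        starts, ends = by_chrom[c]
        j = np.searchsorted(starts, v.pos - 1, side="right") - 1
        keep[i] = j >= 0 and (v.pos - 1) < ends[j]
    return matrix.select_variants(keep)


# ---------------------------------------------------------------------------
# allele-frequency tables
# ---------------------------------------------------------------------------

_AF_KEY_COLS = ["chrom", "pos", "ref", "alt"]


def read_af_table(path) -> AlleleFrequencyTable:
    """Read a tab-separated AF table.

    Layout: optional ``#ancestry_build=<tag>`` comment line, then a header
    ``chrom  pos  ref  alt  <pop1> <pop2> ...`` and one row per variant.
    Empty cells are missing data (masked), not frequency 0.
    """
    path = Path(path)
    build = "unknown"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(f"#{BUILD_HEADER_KEY}="):
            build = first.strip().split("=", 1)[1]
            skip = 1
        else:
            skip = 0
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype={"chrom": str})
    missing_cols = [c for c in _AF_KEY_COLS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: AF table missing columns {missing_cols}")
    pops = [c for c in df.columns if c not in _AF_KEY_COLS]
    if not pops:
        raise ValidationError(f"{path}: AF table has no population columns")
    freqs = df[pops].to_numpy(dtype=float).T  # populations x variants
    with np.errstate(invalid="ignore"):
        bad = (freqs < 0) | (freqs > 1)
    if bad.any():
        row = int(np.where(bad.any(axis=0))[0][0]) + 1
        raise ValidationError(
            f"{path}: frequency outside [0,1] at data row {row}"
        )
    variants = [
        VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt), build)
        for r in df.itertuples()
    ]
    return AlleleFrequencyTable(variants=variants, populations=pops, freqs=freqs)


def write_af_table(aft: AlleleFrequencyTable, path) -> None:
    """Write an AF table; exact float round-trip via repr formatting."""
    builds = {v.build for v in aft.variants}
    build = builds.pop() if len(builds) == 1 else "unknown"
    with open(path, "w") as fh:
        fh.write(f"#{BUILD_HEADER_KEY}={build}\n")
        fh.write("\t".join(_AF_KEY_COLS + list(aft.populations)) + "\n")
        for j, v in enumerate(aft.variants):
            cells = [v.chrom, str(v.pos), v.ref, v.alt]
            for i in range(aft.n_populations):
                if aft.missing[i, j]:
                    cells.append("")
                else:
                    cells.append(repr(float(aft.freqs[i, j])))
            fh.write("\t".join(cells) + "\n")


def read_bed(path, build: str = "unknown") -> GenomicIntervalSet:
    """Read BED (0-based half-open); name column kept when present."""
    intervals: list[tuple] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}: malformed BED line: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if len(parts) >= 4 and parts[3]:
                intervals.append((chrom, start, end, parts[3]))
            else:
                intervals.append((chrom, start, end))
    return GenomicIntervalSet(intervals)


def read_cytoband(path) -> GenomicIntervalSet:
    """Read a UCSC cytoBand.txt table (chrom, start, end, band, stain).

    Interval names are '<chrom without chr><band>', e.g. '1q25.1'.
    """
    intervals: list[tuple] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, band = line.rstrip("\n").split("\t")[:4]
            short = chrom[3:] if chrom.lower().startswith("chr") else chrom
            intervals.append((chrom, int(start), int(end), f"{short}{band}"))
    return GenomicIntervalSet(intervals)


# ---------------------------------------------------------------------------
# model bundles
# ---------------------------------------------------------------------------

def save_model_bundle(models, path) -> None:
    """Serialise a trained model set (single classifier or hierarchy)."""
    payload = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "models": models,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model_bundle(path):
    """Load a model bundle; corrupted or version-mismatched files raise."""
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ModelBundleError(f"cannot load model bundle {path!r}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelBundleError(f"{path!r} is not a model bundle")
    if payload["format_version"] != BUNDLE_FORMAT_VERSION:
        raise ModelBundleError(
            f"bundle format version {payload['format_version']} != "
            f"supported {BUNDLE_FORMAT_VERSION}"
        )
    models = payload["models"]
    _check_bundle_consistency(models)
    return models


def _check_bundle_consistency(models) -> None:
    from .models import HierarchicalModelSet, TrainedClassifier

    def check_one(tc: TrainedClassifier) -> None:
        n = len(tc.feature_list)
        expect = getattr(tc.estimator, "n_features_in_", n)
        if expect != n:
            raise ModelBundleError(
                f"feature-list length {n} inconsistent with estimator "
                f"n_features_in_={expect}"
            )

    if isinstance(models, HierarchicalModelSet):
        check_one(models.continental)
        for parent, sub in models.sub_models.items():
            if parent not in models.continental.label_set:
                raise ModelBundleError(
                    f"sub-model parent {parent!r} not a continental label"
                )
            check_one(sub)
    elif isinstance(models, TrainedClassifier):
        check_one(models)
    else:
        raise ModelBundleError(f"unsupported bundle payload type {type(models)!r}")
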