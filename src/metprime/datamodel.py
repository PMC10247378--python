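"""Shared data model: typed cohort tables, TSV I/O and validation.

Every pipeline stage consumes and produces tab-separated tables with a
header row (UTF-8). The tables cross-link on ``sample_id``. All genomic
coordinates are 0-based half-open (BED convention) — note that the upstream
somatic-pipeline ecosystem is 1-based, so coordinates must be shifted when
importing from it.

Tables
------
samples          one row per tumour sample (cohort label, cancer type, age,
                 purity/ploidy, WGD/MSI/HRD status, biopsy-site class)
treatments       one row per (sample, drug) with mechanism group
segments         purity/ploidy-adjusted copy-number segments with total,
                 minor- and major-allele copy number
mutations        small variants with pyrimidine-centred trinucleotide
                 context (SBS only) and subclonal likelihood
context_counts   sample x channel count matrix over the 96/78/83 channels
signature_profiles  long table (name, mutation_type, channel, prob)
exposures        long table (sample_id, signature, exposure)
sv_clusters      SV event clusters with resolved type, breakpoint count, span
drivers          driver alterations with driver likelihood
arm_definitions  chromosome-arm coordinate table (GRCh37 cytoband-derived
                 table shipped as package data; replaceable)
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .channels import channels_for

logger = logging.getLogger("metprime")

COHORTS = ("primary", "metastatic")
SEXES = ("male", "female", "unknown")
BIOPSY_SITES = ("local", "lymph", "distant", "unknown")
VARIANT_CLASSES = ("SBS", "DBS", "ID", "MNV")
ALTERATION_TYPES = (
    "mutation",
    "amplification",
    "deletion",
    "homozygous_disruption",
    "fusion",
    "noncoding",
)
MUTATION_TYPES = ("SBS", "DBS", "ID")


class SchemaError(ValueError):
    """A table is missing required columns or has wrong types."""


class ValidationError(ValueError):
    """A table violates a documented invariant; message names offending rows."""


# required columns per table (context_counts is wide and checked separately)
TABLE_COLUMNS: dict[str, list[str]] = {
    "samples": [
        "sample_id", "patient_id", "cohort", "cancer_type", "cancer_subtype",
        "age_at_biopsy", "sex", "biopsy_site_class", "tumor_purity",
        "genome_ploidy", "wgd", "msi", "hrd",
    ],
    "treatments": ["sample_id", "drug_name", "mechanism_group", "pre_biopsy"],
    "segments": ["sample_id", "chrom", "start", "end", "cn_total", "cn_minor", "cn_major"],
    "mutations": [
        "sample_id", "chrom", "pos", "ref", "alt", "variant_class",
        "context", "subclonal_likelihood",
    ],
    "signature_profiles": ["name", "mutation_type", "channel", "prob"],
    "exposures": ["sample_id", "signature", "exposure"],
    "sv_clusters": ["sample_id", "resolved_type", "n_sv", "chrom_start", "chrom_end", "length_bp"],
    "drivers": ["sample_id", "gene", "alteration_type", "driver_likelihood"],
    "arm_definitions": ["chrom", "arm", "start", "end"],
}

BOOL_COLUMNS = {
    "samples": ["wgd", "msi", "hrd"],
    "treatments": ["pre_biopsy"],
}

FLOAT_FORMAT = "%.6g"  # fixed serialisation precision for all float columns


@dataclass
class CohortDataset:
    """All cohort tables, cross-linked on sample_id."""

    samples: pd.DataFrame
    treatments: pd.DataFrame = None
    segments: pd.DataFrame = None
    mutations: pd.DataFrame = None
    context_counts: pd.DataFrame = None  # wide: sample_id + channel columns
    signature_profiles: pd.DataFrame = None
    exposures: pd.DataFrame = None
    sv_clusters: pd.DataFrame = None
    drivers: pd.DataFrame = None
    arm_definitions: pd.DataFrame = None
    ground_truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    def table_names(self) -> list[str]:
        return [
            f.name for f in fields(self)
            if f.name != "ground_truth" and getattr(self, f.name) is not None
        ]


def default_arm_table() -> pd.DataFrame:
    """GRCh37 chromosome-arm coordinates (cytoband-derived, centromere gap
    excluded). Replaceable via the ``arm_table`` config key."""
    ref = importlib.resources.files("metprime") / "data" / "grch37_arms.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def _coerce_bools(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    for col in cols:
        if col in df.columns and df[col].dtype != bool:
            df[col] = (
                df[col].astype(str).str.strip().str.lower().map(
                    {"true": True, "false": False, "1": True, "0": False}
                )
            )
            if df[col].isna().any():
                raise SchemaError(f"column {col!r} contains non-boolean values")
            df[col] = df[col].astype(bool)
    return df


def read_table(path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str}, keep_default_na=True)
    if name != "context_counts":
        missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
        if missing:
            raise SchemaError(f"table {name!r} at {path} is missing columns {missing}")
    elif "sample_id" not in df.columns:
        raise SchemaError(f"context_counts at {path} is missing the sample_id column")
    return _coerce_bools(df, BOOL_COLUMNS.get(name, []))


def _fail(table: str, mask: pd.Series, message: str) -> None:
    if mask.any():
        rows = list(np.flatnonzero(np.asarray(mask))[:10])
        raise ValidationError(f"{table}: {message} (rows {rows})")


def validate_samples(samples: pd.DataFrame) -> None:
    dup = samples["sample_id"].duplicated()
    _fail("samples", dup, "duplicate sample_id")
    _fail("samples", ~samples["cohort"].isin(COHORTS), f"cohort not in {COHORTS}")
    _fail("samples", ~samples["sex"].isin(SEXES), f"sex not in {SEXES}")
    _fail("samples", ~samples["biopsy_site_class"].isin(BIOPSY_SITES),
          f"biopsy_site_class not in {BIOPSY_SITES}")
    _fail("samples", (samples["age_at_biopsy"] < 0) | (samples["age_at_biopsy"] > 120),
          "age_at_biopsy outside [0, 120]")
    _fail("samples", (samples["tumor_purity"] <= 0) | (samples["tumor_purity"] > 1),
          "tumor_purity outside (0, 1]")
    _fail("samples", (samples["genome_ploidy"] <= 0) | (samples["genome_ploidy"] >= 16),
          "genome_ploidy outside (0, 16)")


def validate_segments(segments: pd.DataFrame) -> None:
    _fail("segments", segments["start"] >= segments["end"], "start >= end")
    _fail("segments", segments["cn_total"] < 0, "negative cn_total")
    _fail("segments", segments["cn_minor"] > segments["cn_major"] + 1e-9,
          "cn_minor > cn_major")
    ordered = segments.sort_values(["sample_id", "chrom", "start"])
    same = (ordered["sample_id"] == ordered["sample_id"].shift()) & (
        ordered["chrom"] == ordered["chrom"].shift()
    )
    overlap = same & (ordered["start"] < ordered["end"].shift())
    if overlap.any():
        row = ordered[overlap].iloc[0]
        raise ValidationError(
            f"segments: overlapping segments for sample {row['sample_id']!r} "
            f"chromosome {row['chrom']!r}"
        )


_PYRIMIDINE_CONTEXT = r"^[ACGT][CT][ACGT]$"


def validate_mutations(mutations: pd.DataFrame) -> None:
    _fail("mutations", ~mutations["variant_class"].isin(VARIANT_CLASSES),
          f"variant_class not in {VARIANT_CLASSES}")
    _fail("mutations",
          (mutations["subclonal_likelihood"] < 0) | (mutations["subclonal_likelihood"] > 1),
          "subclonal_likelihood outside [0, 1]")
    sbs = mutations["variant_class"] == "SBS"
    bad_ctx = sbs & ~mutations["context"].astype(str).str.match(_PYRIMIDINE_CONTEXT)
    _fail("mutations", bad_ctx, "SBS context is not a pyrimidine-centred trinucleotide")


def validate_signature_profiles(profiles: pd.DataFrame) -> None:
    _fail("signature_profiles", ~profiles["mutation_type"].isin(MUTATION_TYPES),
          f"mutation_type not in {MUTATION_TYPES}")
    _fail("signature_profiles", profiles["prob"] < 0, "negative probability")
    sums = profiles.groupby("name")["prob"].sum()
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad):
        raise ValidationError(
            f"signature_profiles: probabilities do not sum to 1 for {list(bad.index)[:5]}"
        )


def validate_sv_clusters(svs: pd.DataFrame) -> None:
    _fail("sv_clusters", svs["n_sv"] < 1, "n_sv < 1")
    _fail("sv_clusters", svs["length_bp"] < 0, "negative length_bp")


def validate_drivers(drivers: pd.DataFrame) -> None:
    _fail("drivers", ~drivers["alteration_type"].isin(ALTERATION_TYPES),
          f"alteration_type not in {ALTERATION_TYPES}")
    _fail("drivers", (drivers["driver_likelihood"] < 0) | (drivers["driver_likelihood"] > 1),
          "driver_likelihood outside [0, 1]")
    _fail("drivers", drivers["gene"].astype(str).str.len() == 0, "empty gene")


def validate_arm_definitions(arms: pd.DataFrame) -> None:
    _fail("arm_definitions", ~arms["arm"].isin(("p", "q")), "arm not in ('p','q')")
    _fail("arm_definitions", arms["start"] >= arms["end"], "start >= end")


def _validate_foreign_keys(dataset: CohortDataset) -> None:
    known = set(dataset.samples["sample_id"])
    for name in ("treatments", "segments", "mutations", "exposures", "sv_clusters",
                 "drivers", "context_counts"):
        table = getattr(dataset, name)
        if table is None or "sample_id" not in table.columns:
            continue
        unknown = set(table["sample_id"]) - known
        if unknown:
            raise ValidationError(
                f"{name}: sample_id values not present in samples table: "
                f"{sorted(unknown)[:5]}"
            )


def validate_dataset(dataset: CohortDataset) -> None:
    """Run every table validator plus cross-table foreign-key checks."""
    validate_samples(dataset.samples)
    validators = {
        "segments": validate_segments,
        "mutations": validate_mutations,
        "signature_profiles": validate_signature_profiles,
        "sv_clusters": validate_sv_clusters,
        "drivers": validate_drivers,
        "arm_definitions": validate_arm_definitions,
    }
    for name, fn in validators.items():
        table = getattr(dataset, name)
        if table is not None:
            fn(table)
    _validate_foreign_keys(dataset)


def read_cohort(paths: dict[str, str]) -> CohortDataset:
    """Read and validate a cohort dataset from a {table name: path} mapping.

    ``samples`` is required; every other table is optional. When no
    ``arm_definitions`` path is given the shipped GRCh37 arm table is used.
    """
    if "samples" not in paths:
        raise SchemaError("a 'samples' table path is required")
    tables = {name: read_table(path, name) for name, path in paths.items()}
    tables.setdefault("arm_definitions", default_arm_table())
    dataset = CohortDataset(**tables)
    validate_dataset(dataset)
    for name in dataset.table_names():
        logger.info("read %s: %d rows", name, len(getattr(dataset, name)))
    return dataset


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_cohort(dataset: CohortDataset, out_dir) -> dict[str, str]:
    """Write every present table as ``<out_dir>/<name>.tsv``; returns paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name in dataset.table_names():
        path = os.path.join(out_dir, f"{name}.tsv")
        write_table(getattr(dataset, name), path)
        paths[name] = path
    if dataset.ground_truth:
        gt_dir = os.path.join(out_dir, "ground_truth")
        os.makedirs(gt_dir, exist_ok=True)
        for name, df in dataset.ground_truth.items():
            write_table(df, os.path.join(gt_dir, f"{name}.tsv"))
    return paths


def read_cohort_dir(directory) -> CohortDataset:
    """Read a directory written by :func:`write_cohort`."""
    import os

    paths = {}
    for name in TABLE_COLUMNS:
        candidate = os.path.join(directory, f"{name}.tsv")
        if os.path.exists(candidate):
            paths[name] = candidate
    cc = os.path.join(directory, "context_counts.tsv")
    if os.path.exists(cc):
        paths["context_counts"] = cc
    return read_cohort(paths)


def empty_context_counts(sample_ids, mutation_type: str) -> pd.DataFrame:
    cols = list(channels_for(mutation_type))
    df = pd.DataFrame(0, index=pd.Index(sample_ids, name="sample_id"), columns=cols)
    return df.reset_index()
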