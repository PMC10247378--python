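"""Pipeline configuration: every threshold in one place.

Config files are flat YAML key-value mappings; unset keys take the defaults
below, which are the operating thresholds of the published analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml


@dataclass
class Config:
    seed: int = 0
    arm_table: str | None = None  # path to replacement arm TSV; None = shipped GRCh37

    # clonality
    subclonal_threshold: float = 0.8   # subclonal iff likelihood >= this
    clonality_q: float = 0.05
    biopsy_min_per_group: int = 5
    biopsy_adjust: bool = False        # pairwise biopsy-site p-values unadjusted

    # karyotype / instability
    karyotype_q: float = 0.01
    arm_diff_threshold: float = 0.25   # |mean normalized arm ploidy diff| must exceed
    raw_arm_ploidy: bool = False       # compare raw arm ploidies instead of classes
    modal_tie_lower: bool = True       # coverage ties broken toward the lower CN
    instability_q: float = 0.01
    loh_minor_max: float = 0.25        # LOH iff minor CN < this ...
    loh_major_min: float = 0.8         # ... and major CN >= this
    wgd_min_autosomes: int = 10        # WGD iff MORE than this many autosomes ...
    wgd_cn_threshold: float = 1.5      # ... have chromosome CN above this

    # signatures
    cosine_match_threshold: float = 0.85
    clustering_linkage: str = "average"  # {average, complete, ward}
    signature_q: float = 0.05
    log2fc_threshold: float = 0.4
    relative_diff_threshold: float = 0.01
    hypermutator_sbs: float = 10_000
    hypermutator_dbs: float = 500
    hypermutator_id: float = 1_000
    hypermutator_min_samples: int = 5

    # clock-like
    tmb_exclude_above: float = 30_000
    sbs1_exclude_above: float = 5_000
    n_bootstrap: int = 100
    bootstrap_fraction: float = 0.75
    min_clock_points: int = 20
    pearson_gate: float = 0.1
    clock_p_threshold: float = 0.01
    fc_age_min: int = 40
    fc_age_max: int = 80
    literal_1_over_40: bool = False    # reproduce the printed 1/40 coefficient

    # SV burden
    sv_small_max_bp: int = 10_000      # small iff length < this
    sv_complex_large_min: int = 20     # large complex iff n_sv >= this
    sv_q: float = 0.05
    sv_fc_high: float = 1.2
    sv_fc_low: float = 0.8
    lm_min_samples: int = 30
    lm_regression_p: float = 0.01
    lm_coef_p: float = 0.01
    gene_min_true_combined: int = 15
    gene_min_true_cohort: int = 10
    bool_min_true_fraction: float = 0.05
    standardize_numeric: bool = False

    # drivers / TEDs
    driver_likelihood_min: float = 0.5  # retained iff likelihood > this (strict)
    driver_count_q: float = 0.01
    driver_enrichment_q: float = 0.01
    gene_min_mutated: int = 5
    ted_min_patients: int = 10
    ted_q_coding: float = 0.05
    ted_q_noncoding: float = 0.1
    ted_noncoding_min_mutated: int = 3
    exclusive_max_frequency: float = 0.05
    cn_amp_diff: float = 2.5           # amplified iff gene ploidy - mean > this
    cn_del_below: float = 0.3          # deleted iff gene ploidy < this
    untreated_strict: bool = False
    ted_candidate_min_altered: int = 3

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path=None, **overrides) -> Config:
    """Load a flat YAML config; unset keys take the documented defaults.

    Unknown keys raise a ``ValueError`` listing the valid keys.
    """
    values: dict = {}
    if path is not None:
        with open(path) as handle:
            try:
                loaded = yaml.safe_load(handle)
            except yaml.YAMLError as exc:
                raise ValueError(f"malformed config file {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must be a flat key-value mapping")
        values.update(loaded)
    values.update(overrides)
    valid = {f.name for f in fields(Config)}
    unknown = sorted(set(values) - valid)
    if unknown:
        raise ValueError(
            f"unknown config keys {unknown}; valid keys: {sorted(valid)}"
        )
    return Config(**values)
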