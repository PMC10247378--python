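"""Synthetic two-cohort generator with known ground truth.

The real study's cohorts are controlled-access, so every pipeline stage is
exercised on synthetic cohorts that emulate their statistical structure:
per-sample metadata, copy-number segments with arm-level events and WGD,
small-variant catalogues whose SBS1 burden grows linearly with age,
signature exposures with configurable cohort shifts, negative-binomial SV
burdens with feature effects on the log10 scale, and driver/treatment
tables with injected treatment-associated odds ratios. Every injected
effect is recorded in ground-truth tables so downstream stages have a
parameter-recovery surface.

Mutation contexts are generated directly as channel labels (all downstream
computation consumes channels, not coordinates); genomic positions are
drawn uniformly per chromosome purely to satisfy the schema. Randomness is
one global stream split per sample by a stable hash of the sample id, so
adding samples never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import dbs78_channels, id83_channels, parse_sbs_channel, sbs96_channels
from .datamodel import CohortDataset, default_arm_table

# ---------------------------------------------------------------------------
# canonical-shape synthetic signature profiles


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / v.sum()


def base_profile(name: str) -> tuple[str, np.ndarray]:
    """Built-in synthetic signature shapes (mutation_type, channel probs).

    Shapes imitate the qualitative structure of well-known processes
    (clock-like NCG>NTG peaks, APOBEC TCN peaks, flat clock-like SBS5, a
    C>A-heavy therapy-like shape, characteristic DBS/ID peaks); they are
    synthetic stand-ins, not the reference catalogue itself.
    """
    sbs = list(sbs96_channels())
    dbs = list(dbs78_channels())
    ids = list(id83_channels())
    if name == "SBS1":
        v = np.full(len(sbs), 0.10 / (len(sbs) - 4))
        for ctx in ("A[C>T]G", "C[C>T]G", "G[C>T]G", "T[C>T]G"):
            v[sbs.index(ctx)] = 0.225
        return "SBS", _normalize(v)
    if name == "SBS5":
        v = np.ones(len(sbs))
        for i, ch in enumerate(sbs):  # mild T>C tilt
            if "[T>C]" in ch:
                v[i] = 2.0
        return "SBS", _normalize(v)
    if name == "APOBEC":
        v = np.full(len(sbs), 0.08 / (len(sbs) - 4))
        for ctx in ("T[C>T]A", "T[C>T]T", "T[C>G]A", "T[C>G]T"):
            v[sbs.index(ctx)] = 0.23
        return "SBS", _normalize(v)
    if name == "PLATINUM":
        v = np.full(len(sbs), 0.3 / (len(sbs) - 16))
        for i, ch in enumerate(sbs):
            if "[C>A]" in ch and ch[0] in "CG":
                v[i] = 0.7 / 8
        return "SBS", _normalize(v)
    if name == "DBS_CLOCK":
        v = np.ones(len(dbs))
        return "DBS", _normalize(v)
    if name == "DBS_PLATINUM":
        v = np.full(len(dbs), 0.2 / (len(dbs) - 2))
        v[dbs.index("CT>AA")] = 0.4
        v[dbs.index("CT>AC")] = 0.4
        return "DBS", _normalize(v)
    if name == "ID_CLOCK":
        v = np.ones(len(ids))
        return "ID", _normalize(v)
    if name == "ID_SLIPPAGE":
        v = np.full(len(ids), 0.2 / (len(ids) - 6))
        for ch in (f"1:Del:T:{n}" for n in range(6)):
            v[ids.index(ch)] = 0.8 / 6
        return "ID", _normalize(v)
    raise ValueError(f"unknown base profile {name!r}")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SignatureSpec:
    """One simulated mutational process and its cohort exposure means."""

    name: str
    profile: str                 # base_profile key
    aetiology: str
    mean_primary: float
    mean_metastatic: float
    dispersion: float = 5.0      # gamma shape; larger = less overdispersed


@dataclass
class ArmEventSpec:
    arm: str                     # e.g. "5q"
    kind: str                    # "loss" or "gain"
    p_primary: float
    p_metastatic: float


@dataclass
class DriverGeneSpec:
    gene: str
    alteration_type: str
    p_primary: float
    p_metastatic: float
    treatment: str | None = None  # mechanism group carrying the injected OR
    odds_ratio: float = 1.0       # treated odds = baseline odds x this


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults emulate the published contrasts: higher metastatic clonality,
    more arm losses, more frequent WGD, APOBEC- and therapy-driven
    signature shifts, a 1.5x SBS1 age-rate fold change, HRD-driven small
    deletion burden and a hormone-therapy-enriched driver.
    """

    seed: int = 0
    cancer_types: tuple[str, ...] = ("breast", "prostate")
    n_primary: int = 150
    n_metastatic: int = 150
    age_mean: float = 62.0
    age_sd: float = 11.0
    age_min: float = 30.0
    age_max: float = 90.0

    clonal_fraction_primary: float = 0.85
    clonal_fraction_metastatic: float = 0.92

    sbs1_slope_primary: float = 4.0            # mutations / year
    sbs1_fold_change_metastatic: float = 1.5
    sbs1_noise_dispersion: float = 30.0

    wgd_p_primary: float = 0.25
    wgd_p_metastatic: float = 0.5
    arm_event_base_p: float = 0.05
    arm_events: tuple[ArmEventSpec, ...] = (
        ArmEventSpec("5q", "loss", 0.10, 0.45),
        ArmEventSpec("8q", "gain", 0.15, 0.40),
    )
    loh_segment_p: float = 0.08

    signatures: tuple[SignatureSpec, ...] = (
        SignatureSpec("SBS5_denovo", "SBS5", "clock-like SBS5/40", 600, 700),
        SignatureSpec("APOBEC_denovo", "APOBEC", "APOBEC", 150, 450),
        SignatureSpec("PLATINUM_denovo", "PLATINUM", "platinum", 0, 250),
        SignatureSpec("DBS_clock_denovo", "DBS_CLOCK", "DBS clock-like", 30, 35),
        SignatureSpec("DBS_platinum_denovo", "DBS_PLATINUM", "platinum DBS", 0, 40),
        SignatureSpec("ID_clock_denovo", "ID_CLOCK", "ID clock-like", 80, 90),
        SignatureSpec("ID_slippage_denovo", "ID_SLIPPAGE", "slippage ID", 40, 120),
    )

    hrd_p: float = 0.12
    msi_p: float = 0.03

    # log10-scale intercepts per SV class and feature coefficients
    sv_log10_means: dict = field(default_factory=lambda: {
        "del_small": 0.9, "del_large": 0.7, "dup_small": 0.6, "dup_large": 0.6,
        "complex_small": 0.5, "complex_large": 0.2, "line": 0.4,
    })
    sv_metastatic_shift: dict = field(default_factory=lambda: {
        "del_small": 0.35, "dup_small": 0.3, "complex_large": 0.25,
    })
    sv_feature_coefficients: dict = field(default_factory=lambda: {
        ("del_small", "hrd"): 0.5, ("dup_small", "hrd"): 0.45,
        ("complex_small", "genome_ploidy"): 0.12,
    })
    sv_dispersion: float = 4.0

    treatment_groups: dict = field(default_factory=lambda: {
        "platinum": 0.4, "hormone": 0.35, "taxane": 0.3,
    })
    driver_genes: tuple[DriverGeneSpec, ...] = (
        DriverGeneSpec("TP53", "mutation", 0.30, 0.45),
        DriverGeneSpec("PIK3CA", "mutation", 0.20, 0.25),
        DriverGeneSpec("MYC", "amplification", 0.10, 0.20),
        DriverGeneSpec("PTEN", "deletion", 0.08, 0.12),
        DriverGeneSpec("AR", "mutation", 0.02, 0.05, treatment="hormone",
                       odds_ratio=8.0),
        DriverGeneSpec("ESR1", "mutation", 0.02, 0.04, treatment="hormone",
                       odds_ratio=6.0),
    )

    def validate(self) -> None:
        if self.n_primary <= 0 or self.n_metastatic <= 0:
            raise ValueError("cohort sizes must be positive")
        for spec in self.driver_genes:
            if spec.odds_ratio <= 0:
                raise ValueError(f"odds ratio must be positive for {spec.gene}")
        for spec in self.arm_events:
            for p in (spec.p_primary, spec.p_metastatic):
                if not 0 <= p <= 1:
                    raise ValueError(f"arm event probability out of [0,1]: {p}")


def sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Per-sample generator split from the run seed by a stable hash."""
    digest = hashlib.blake2b(sample_id.encode(), digest_size=4).digest()
    return np.random.default_rng([seed, int.from_bytes(digest, "big")])


def injected_odds_probability(baseline_p: float, odds_ratio: float) -> float:
    """Probability after scaling the baseline odds by ``odds_ratio``."""
    odds = baseline_p / (1 - baseline_p) * odds_ratio
    return odds / (1 + odds)


# ---------------------------------------------------------------------------
# per-sample generators


def simulate_mutation_catalog(sample: dict, config: SimulationConfig,
                              rng: np.random.Generator):
    """Mutation records + per-signature true exposures for one sample.

    SBS1 mutations are Poisson with mean slope x age x cohort fold change;
    every other process draws a gamma-Poisson (negative binomial) count
    around its cohort mean. Channels are multinomial draws from the
    process's profile; subclonal likelihoods come from a two-component
    uniform mixture with the cohort's clonal fraction.
    """
    cohort = sample["cohort"]
    fc = config.sbs1_fold_change_metastatic if cohort == "metastatic" else 1.0
    clonal_frac = (config.clonal_fraction_metastatic if cohort == "metastatic"
                   else config.clonal_fraction_primary)
    sbs1_mean = config.sbs1_slope_primary * sample["age_at_biopsy"] * fc
    counts: dict[str, int] = {"SBS1_denovo": int(rng.poisson(sbs1_mean))}
    profiles: dict[str, tuple[str, np.ndarray]] = {"SBS1_denovo": base_profile("SBS1")}
    for spec in config.signatures:
        mean = spec.mean_metastatic if cohort == "metastatic" else spec.mean_primary
        if spec.aetiology == "platinum" or spec.profile.endswith("PLATINUM"):
            # therapy signatures only appear in platinum-treated samples
            if "platinum" not in sample.get("mechanisms", ()):
                mean = 0.0
        if mean <= 0:
            counts[spec.name] = 0
        else:
            lam = rng.gamma(spec.dispersion, mean / spec.dispersion)
            counts[spec.name] = int(rng.poisson(lam))
        profiles[spec.name] = base_profile(spec.profile)
    records = []
    for name, count in counts.items():
        if count == 0:
            continue
        mutation_type, probs = profiles[name]
        channels = {"SBS": sbs96_channels(), "DBS": dbs78_channels(),
                    "ID": id83_channels()}[mutation_type]
        drawn = rng.multinomial(count, probs)
        for channel_idx in np.repeat(np.arange(len(channels)), drawn):
            channel = channels[channel_idx]
            if mutation_type == "SBS":
                context, ref, alt = parse_sbs_channel(channel)
            elif mutation_type == "DBS":
                context, (ref, alt) = "", channel.split(">")
            else:
                context, ref, alt = "", "N", "N"
            clonal = rng.random() < clonal_frac
            likelihood = rng.uniform(0.0, 0.8) if clonal else rng.uniform(0.8, 1.0)
            records.append({
                "sample_id": sample["sample_id"],
                "chrom": str(rng.integers(1, 23)),
                "pos": int(rng.integers(0, 100_000_000)),
                "ref": ref, "alt": alt,
                "variant_class": mutation_type,
                "context": context,
                "subclonal_likelihood": round(float(likelihood), 6),
                "signature": name,
                "channel": channel,
            })
    return records, counts


def simulate_cn_segments(sample: dict, config: SimulationConfig,
                         arm_table: pd.DataFrame, rng: np.random.Generator,
                         arm_event_draws: dict[str, int]) -> list[dict]:
    """Copy-number segments: WGD doubles the baseline; arm events shift
    whole arms by +-1; each arm is split into 2-3 abutting segments."""
    baseline = 4 if sample["wgd"] else 2
    rows = []
    for _, arm in arm_table.iterrows():
        name = f"{arm['chrom']}{arm['arm']}"
        cn = baseline + arm_event_draws.get(name, 0)
        cn = max(cn, 0)
        n_seg = int(rng.integers(2, 4))
        cuts = np.sort(rng.integers(arm["start"] + 1, arm["end"], size=n_seg - 1))
        bounds = [int(arm["start"]), *[int(c) for c in cuts], int(arm["end"])]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            total = cn + float(rng.normal(0, 0.08))
            if rng.random() < config.loh_segment_p and cn >= 1:
                minor, major = 0.05, max(total - 0.05, 0.9)
            else:
                minor = max(min(total / 2, 1.0), 0.0)
                major = max(total - minor, minor)
            rows.append({"sample_id": sample["sample_id"], "chrom": str(arm["chrom"]),
                         "start": lo, "end": hi,
                         "cn_total": round(max(total, 0.0), 4),
                         "cn_minor": round(minor, 4), "cn_major": round(major, 4)})
    return rows


def sv_burden_means(sample: dict, config: SimulationConfig) -> dict[str, float]:
    """Expected SV count per class: log10 mean linear in sample features."""
    means = {}
    for sv_type, b0 in config.sv_log10_means.items():
        log10_mu = b0
        if sample["cohort"] == "metastatic":
            log10_mu += config.sv_metastatic_shift.get(sv_type, 0.0)
        for (t, feature), coef in config.sv_feature_coefficients.items():
            if t != sv_type:
                continue
            value = {"hrd": float(sample["hrd"]), "msi": float(sample["msi"]),
                     "genome_ploidy": sample["genome_ploidy"],
                     "n_treatments": float(len(sample.get("mechanisms", ())))}[feature]
            log10_mu += coef * value
        means[sv_type] = 10.0 ** log10_mu - 1.0
    return means


def simulate_sv_clusters(sample: dict, config: SimulationConfig,
                         rng: np.random.Generator) -> list[dict]:
    """SV cluster records drawn negative-binomial per class.

    Record attributes (resolved type, span, breakpoint count) are chosen so
    the classifier maps each record back to its generating class.
    """
    rows = []
    for sv_type, mu in sv_burden_means(sample, config).items():
        mu = max(mu, 0.0)
        size = config.sv_dispersion
        count = int(rng.negative_binomial(size, size / (size + mu))) if mu > 0 else 0
        for _ in range(count):
            chrom = str(rng.integers(1, 23))
            if sv_type.startswith(("del", "dup")):
                token = "DEL" if sv_type.startswith("del") else "DUP"
                small = sv_type.endswith("small")
                length = int(rng.integers(50, 10_000)) if small \
                    else int(rng.integers(10_000, 5_000_000))
                rows.append({"sample_id": sample["sample_id"], "resolved_type": token,
                             "n_sv": 1, "chrom_start": chrom, "chrom_end": chrom,
                             "length_bp": length})
            elif sv_type.startswith("complex"):
                small = sv_type.endswith("small")
                n_sv = int(rng.integers(2, 20)) if small else int(rng.integers(20, 80))
                rows.append({"sample_id": sample["sample_id"],
                             "resolved_type": "COMPLEX", "n_sv": n_sv,
                             "chrom_start": chrom, "chrom_end": str(rng.integers(1, 23)),
                             "length_bp": int(rng.integers(1000, 50_000_000))})
            else:
                rows.append({"sample_id": sample["sample_id"], "resolved_type": "LINE",
                             "n_sv": 1, "chrom_start": chrom, "chrom_end": chrom,
                             "length_bp": int(rng.integers(300, 6000))})
    return rows


def simulate_drivers(sample: dict, config: SimulationConfig,
                     rng: np.random.Generator) -> list[dict]:
    """Driver events with likelihoods; treatment-linked genes get their
    baseline odds scaled by the injected odds ratio when the sample's
    mechanisms include the linked treatment."""
    rows = []
    for spec in config.driver_genes:
        p = spec.p_metastatic if sample["cohort"] == "metastatic" else spec.p_primary
        if spec.treatment is not None and spec.treatment in sample.get("mechanisms", ()):
            p = injected_odds_probability(p, spec.odds_ratio)
        if rng.random() < p:
            rows.append({"sample_id": sample["sample_id"], "gene": spec.gene,
                         "alteration_type": spec.alteration_type,
                         "driver_likelihood": round(float(rng.uniform(0.6, 1.0)), 4)})
        # low-likelihood passenger noise, filtered out downstream
        if rng.random() < 0.05:
            rows.append({"sample_id": sample["sample_id"], "gene": spec.gene,
                         "alteration_type": spec.alteration_type,
                         "driver_likelihood": round(float(rng.uniform(0.0, 0.5)), 4)})
    return rows


# ---------------------------------------------------------------------------
# full-cohort assembly


def _context_count_matrix(mutations: pd.DataFrame, sample_ids) -> pd.DataFrame:
    all_channels = (list(sbs96_channels()) + list(dbs78_channels())
                    + list(id83_channels()))
    mat = pd.DataFrame(0, index=pd.Index(sample_ids, name="sample_id"),
                       columns=all_channels)
    if len(mutations):
        counts = mutations.groupby(["sample_id", "channel"]).size().unstack(
            fill_value=0)
        mat.loc[counts.index, counts.columns] = counts
    return mat.reset_index()


def simulate_cohort(config: SimulationConfig | None = None) -> CohortDataset:
    """Generate the full synthetic dataset plus ground-truth tables."""
    config = config or SimulationConfig()
    config.validate()
    arm_table = default_arm_table()
    arm_table = arm_table[arm_table["chrom"].isin([str(i) for i in range(1, 23)])]

    sample_rows, treatment_rows = [], []
    mutation_rows, segment_rows, sv_rows, driver_rows, exposure_rows = [], [], [], [], []
    for cancer_type in config.cancer_types:
        for cohort, n in (("primary", config.n_primary),
                          ("metastatic", config.n_metastatic)):
            for i in range(n):
                sid = f"{cancer_type[:2].upper()}-{cohort[:3].upper()}-{i:04d}"
                rng = sample_rng(config.seed, sid)
                age = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                                    config.age_min, config.age_max))
                wgd = bool(rng.random() < (config.wgd_p_metastatic
                                           if cohort == "metastatic"
                                           else config.wgd_p_primary))
                mechanisms = tuple(
                    m for m, p in sorted(config.treatment_groups.items())
                    if cohort == "metastatic" and rng.random() < p)
                sample = {
                    "sample_id": sid, "patient_id": f"PT-{sid}", "cohort": cohort,
                    "cancer_type": cancer_type, "cancer_subtype": "",
                    "age_at_biopsy": round(age, 1),
                    "sex": "female" if rng.random() < 0.5 else "male",
                    "biopsy_site_class": ("unknown" if cohort == "primary" else
                                          str(rng.choice(["local", "lymph", "distant"],
                                                         p=[0.3, 0.3, 0.4]))),
                    "tumor_purity": round(float(rng.uniform(0.3, 1.0)), 3),
                    "wgd": wgd,
                    "msi": bool(rng.random() < config.msi_p),
                    "hrd": bool(rng.random() < config.hrd_p),
                    "mechanisms": mechanisms,
                }
                arm_draws = {}
                for _, arm in arm_table.iterrows():
                    name = f"{arm['chrom']}{arm['arm']}"
                    p_gain = p_loss = config.arm_event_base_p
                    for spec in config.arm_events:
                        if spec.arm == name:
                            p = (spec.p_metastatic if cohort == "metastatic"
                                 else spec.p_primary)
                            if spec.kind == "gain":
                                p_gain = p
                            else:
                                p_loss = p
                    u = rng.random()
                    if u < p_gain:
                        arm_draws[name] = 1
                    elif u < p_gain + p_loss:
                        arm_draws[name] = -1
                segs = simulate_cn_segments(sample, config, arm_table, rng, arm_draws)
                lengths = np.array([s["end"] - s["start"] for s in segs], dtype=float)
                cns = np.array([s["cn_total"] for s in segs])
                sample["genome_ploidy"] = round(float(np.average(cns, weights=lengths)), 3)
                segment_rows.extend(segs)

                muts, true_counts = simulate_mutation_catalog(sample, config, rng)
                mutation_rows.extend(muts)
                for name, count in true_counts.items():
                    exposure_rows.append({"sample_id": sid, "signature": name,
                                          "exposure": count})
                sv_rows.extend(simulate_sv_clusters(sample, config, rng))
                driver_rows.extend(simulate_drivers(sample, config, rng))
                for mech in mechanisms:
                    treatment_rows.append({"sample_id": sid,
                                           "drug_name": f"{mech}_drug",
                                           "mechanism_group": mech,
                                           "pre_biopsy": True})
                sample_rows.append({k: v for k, v in sample.items()
                                    if k != "mechanisms"})

    mutations = pd.DataFrame(mutation_rows)
    samples = pd.DataFrame(sample_rows)
    context_counts = _context_count_matrix(mutations, samples["sample_id"])
    signature_profiles = simulate_denovo_profiles(config)

    ground_truth = {
        "sbs1": pd.DataFrame([{
            "slope_primary": config.sbs1_slope_primary,
            "fold_change_metastatic": config.sbs1_fold_change_metastatic,
        }]),
        "clonality": pd.DataFrame([{
            "clonal_fraction_primary": config.clonal_fraction_primary,
            "clonal_fraction_metastatic": config.clonal_fraction_metastatic,
        }]),
        "arm_events": pd.DataFrame([s.__dict__ for s in config.arm_events]),
        "signatures": pd.DataFrame([s.__dict__ for s in config.signatures]),
        "sv_effects": pd.DataFrame(
            [{"sv_type": t, "feature": f, "coefficient": c}
             for (t, f), c in config.sv_feature_coefficients.items()]),
        "driver_odds": pd.DataFrame([s.__dict__ for s in config.driver_genes]),
        "wgd": pd.DataFrame([{"p_primary": config.wgd_p_primary,
                              "p_metastatic": config.wgd_p_metastatic}]),
    }
    dataset = CohortDataset(
        samples=samples,
        treatments=pd.DataFrame(treatment_rows,
                                columns=["sample_id", "drug_name",
                                         "mechanism_group", "pre_biopsy"]),
        segments=pd.DataFrame(segment_rows),
        mutations=mutations.drop(columns=["signature", "channel"],
                                 errors="ignore") if len(mutations) else mutations,
        context_counts=context_counts,
        signature_profiles=signature_profiles,
        exposures=pd.DataFrame(exposure_rows),
        sv_clusters=pd.DataFrame(sv_rows, columns=["sample_id", "resolved_type",
                                                   "n_sv", "chrom_start",
                                                   "chrom_end", "length_bp"]),
        drivers=pd.DataFrame(driver_rows, columns=["sample_id", "gene",
                                                   "alteration_type",
                                                   "driver_likelihood"]),
        arm_definitions=arm_table.reset_index(drop=True),
        ground_truth=ground_truth,
    )
    dataset.mutation_signatures = (mutations[["sample_id", "signature"]]
                                   if len(mutations) else pd.DataFrame())
    return dataset


def simulate_denovo_profiles(config: SimulationConfig,
                             noise: float = 2000.0) -> pd.DataFrame:
    """Fabricated "de novo" profiles: base shapes + Dirichlet perturbation.

    ``noise`` is the Dirichlet concentration multiplier; larger = closer to
    the base shape.
    """
    rng = np.random.default_rng([config.seed, 7_654_321])
    rows = []
    specs = [("SBS1_denovo", "SBS1")] + [(s.name, s.profile) for s in config.signatures]
    for name, key in specs:
        mutation_type, probs = base_profile(key)
        perturbed = rng.dirichlet(probs * noise + 1e-3)
        channels = {"SBS": sbs96_channels(), "DBS": dbs78_channels(),
                    "ID": id83_channels()}[mutation_type]
        perturbed = perturbed / perturbed.sum()
        for ch, p in zip(channels, perturbed):
            rows.append({"name": name, "mutation_type": mutation_type,
                         "channel": ch, "prob": p})
    return pd.DataFrame(rows)


def aetiology_map_for(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth aetiology map for the simulated signatures."""
    rows = [{"signature": "SBS1_denovo", "aetiology": "clock-like SBS1",
             "provenance": "reference_match"}]
    rows += [{"signature": s.name, "aetiology": s.aetiology,
              "provenance": "reference_match"} for s in config.signatures]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# targeted simulators for stage-level parameter recovery


def simulate_clock_points(n: int, slope: float, intercept: float, fold_change: float,
                          noise_sd: float, seed: int, age_min: float = 30.0,
                          age_max: float = 80.0) -> pd.DataFrame:
    """(age, count) points for one cohort pair: primary at the base rate,
    metastatic at slope x fold change; gaussian noise truncated at zero."""
    rng = np.random.default_rng(seed)
    rows = []
    for cohort, fc in (("primary", 1.0), ("metastatic", fold_change)):
        ages = rng.uniform(age_min, age_max, size=n)
        counts = np.clip(slope * fc * ages + intercept
                         + rng.normal(0, noise_sd, size=n), 0, None)
        for a, c in zip(ages, counts):
            rows.append({"cohort": cohort, "age_at_biopsy": float(a),
                         "sbs1_count": float(c)})
    return pd.DataFrame(rows)


def simulate_sv_feature_cohort(n_per_cohort: int, coefficients: dict[str, float],
                               metastatic_shift: float, seed: int,
                               noise_sd: float = 0.25,
                               confounded_feature: str | None = None
                               ) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    """Feature matrix + log-linear SV burden for the three-LM screen.

    ``coefficients`` maps boolean feature names to log10-scale effects.
    ``confounded_feature`` names a boolean feature that differs in
    prevalence between cohorts but has no burden effect. Returns (burden
    counts, features, cohort labels) indexed by sample id.
    """
    rng = np.random.default_rng(seed)
    ids = [f"S{i:04d}" for i in range(2 * n_per_cohort)]
    cohort = pd.Series(["metastatic"] * n_per_cohort + ["primary"] * n_per_cohort,
                       index=ids, name="cohort")
    feats = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    feats["genome_ploidy"] = rng.normal(2.8, 0.6, size=len(ids)).clip(1.5, 6)
    for name in coefficients:
        feats[name] = rng.binomial(1, 0.25, size=len(ids))
    if confounded_feature is not None:
        prev = np.where(cohort == "metastatic", 0.5, 0.1)
        feats[confounded_feature] = rng.binomial(1, prev)
    log_mu = 0.8 + sum(coef * feats[name] for name, coef in coefficients.items())
    log_mu = log_mu + np.where(cohort == "metastatic", metastatic_shift, 0.0)
    z = log_mu + rng.normal(0, noise_sd, size=len(ids))
    burden = pd.Series(np.round(10.0 ** z - 1).clip(0).astype(int), index=feats.index,
                       name="burden")
    return burden, feats, cohort


def simulate_ted_patients(n_treated: int, n_untreated: int, n_genes: int,
                          baseline_p: float, injected: dict[str, float],
                          seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient x gene alteration table for the TED test.

    ``injected`` maps gene names (must be among gene_0..gene_{n-1}) to odds
    ratios applied in the treated group. Returns (treated, untreated) boolean
    DataFrames.
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i}" for i in range(n_genes)]
    treated = pd.DataFrame(index=[f"T{i}" for i in range(n_treated)], columns=genes)
    untreated = pd.DataFrame(index=[f"U{i}" for i in range(n_untreated)], columns=genes)
    for gene in genes:
        p_t = injected_odds_probability(baseline_p, injected.get(gene, 1.0))
        treated[gene] = rng.binomial(1, p_t, size=n_treated).astype(bool)
        untreated[gene] = rng.binomial(1, baseline_p, size=n_untreated).astype(bool)
    return treated, untreated
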