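"""Seeded synthetic-data generators for every pipeline input.

These emulate the statistical structure of the four study inputs —
censored latency trials, duplicate enzymology plates with reference
samples, triplicate qPCR wells, and phase-plateau OCR traces — so that
every analysis stage is exercisable without animal data. Group effects
default to the qualitative direction seen in the alpha-synuclein
overexpressing (ASO) specific-pathogen-free (SPF) mice — lower task
completion probability, higher uncoupled respiration — without asserting
any published magnitude.

One master seed expands into independent per-generator streams via
``numpy`` SeedSequence-style keyed generators ``default_rng([seed, k])``,
so adding a generator never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import DEFAULT_CENSOR_POINT
from .bioenergetics import ASSAYS
from .respirometry import PHASE_ORDER

# fixed per-generator stream keys
_STREAM_TRIALS = 1
_STREAM_ENZYMES = 2
_STREAM_QPCR = 3
_STREAM_OCR = 4


@dataclass
class BehaviorGroupConfig:
    omega: float
    mu: float
    sigma: float
    n_animals: int
    trials_per_animal: int = 3  # 1-3 in the study design


@dataclass
class SyntheticConfig:
    """Defaults mirror the study design: four genotype x microbiome
    groups, 16 mice per group, 3 trials each, 60-s ceiling; two assay
    plates with five reference samples; triplicate qPCR; quintuplicate
    OCR wells."""

    seed: int = 0
    censor_point: float = DEFAULT_CENSOR_POINT
    behavior: dict = field(default_factory=lambda: {
        # (genotype, condition): completion prob, log-latency location/scale
        ("WT", "SPF"): BehaviorGroupConfig(0.95, math.log(8.0), 0.45, 16),
        ("ASO", "SPF"): BehaviorGroupConfig(0.60, math.log(20.0), 0.55, 16),
        ("WT", "GF"): BehaviorGroupConfig(0.95, math.log(8.0), 0.45, 16),
        ("ASO", "GF"): BehaviorGroupConfig(0.90, math.log(10.0), 0.50, 16),
    })
    tests: tuple = ("beam", "pole")
    # enzymology: cohort mean activity (nmol/min/mg) and CV per assay
    enzyme_means: dict = field(default_factory=lambda: {
        "CI": 20.0, "CII": 12.0, "CIV": 30.0, "CS": 100.0})
    enzyme_cv: float = 0.15
    duplicate_cv: float = 0.05
    nonspecific_fraction: float = 0.10
    n_plates: int = 2
    plate_effects: tuple = (1.0, 1.25)
    references_per_plate: int = 5
    # qPCR
    qpcr_mtdnacn: dict = field(default_factory=lambda: {
        ("WT", "SPF"): 600.0, ("ASO", "SPF"): 900.0,
        ("WT", "GF"): 600.0, ("ASO", "GF"): 650.0})
    qpcr_ct_anchor: float = 24.0  # nuclear-amplicon Ct center
    qpcr_ct_noise: float = 0.15
    # OCR: per-group phase plateau means, pmol O2/min (Complex I substrate)
    ocr_plateaus: dict = field(default_factory=lambda: {
        ("WT", "SPF"): {"substrate": 50.0, "adp": 150.0, "oligomycin": 60.0,
                        "fccp": 200.0, "rot_aa": 10.0},
        ("ASO", "SPF"): {"substrate": 60.0, "adp": 190.0, "oligomycin": 70.0,
                         "fccp": 280.0, "rot_aa": 10.0},
        ("WT", "GF"): {"substrate": 50.0, "adp": 150.0, "oligomycin": 60.0,
                       "fccp": 200.0, "rot_aa": 10.0},
        ("ASO", "GF"): {"substrate": 52.0, "adp": 155.0, "oligomycin": 62.0,
                        "fccp": 210.0, "rot_aa": 10.0},
    })
    ocr_noise_sd: float = 5.0
    ocr_cycles_per_phase: int = 3
    wells_per_mouse: int = 5
    protein_mean_ug: float = 8.0
    protein_sd_ug: float = 1.0
    ocr_mice_per_group: int = 8

    def __post_init__(self) -> None:
        for g, cfg in self.behavior.items():
            if not 0 <= cfg.omega <= 1:
                raise ValueError(f"omega out of [0,1] for group {g}")
            if not 1 <= cfg.trials_per_animal <= 3:
                raise ValueError("trials_per_animal must be in 1..3")
        if len(self.plate_effects) != self.n_plates:
            raise ValueError("plate_effects length must equal n_plates")


def _animal_ids(config: SyntheticConfig):
    out = []
    for (gen, cond), gcfg in config.behavior.items():
        for i in range(gcfg.n_animals):
            out.append((f"{gen}-{cond}-{i + 1:03d}", gen, cond, gcfg))
    return out


def simulate_trials(config: SyntheticConfig) -> pd.DataFrame:
    """Forward-simulate censored latency trials for every group and test.

    Per trial: Bernoulli(omega) completion; completers draw
    LogNormal(mu, sigma) censored at the ceiling; failures score the
    ceiling exactly.
    """
    rng = np.random.default_rng([config.seed, _STREAM_TRIALS])
    c = config.censor_point
    rows = []
    for test in config.tests:
        for animal_id, gen, cond, gcfg in _animal_ids(config):
            for trial in range(1, gcfg.trials_per_animal + 1):
                if rng.random() < gcfg.omega:
                    y = min(rng.lognormal(gcfg.mu, gcfg.sigma), c)
                else:
                    y = c
                rows.append({
                    "animal_id": animal_id, "genotype": gen, "condition": cond,
                    "test": test, "trial": trial, "latency_s": round(float(y), 3),
                })
    df = pd.DataFrame(rows)
    # rounding may not touch the ceiling; censored iff scored at ceiling
    df.loc[df["latency_s"] >= c, "latency_s"] = c
    return df


def simulate_enzyme_plates(config: SyntheticConfig) -> pd.DataFrame:
    """Duplicate enzymology wells with multiplicative plate effects.

    Animals are split across plates; each plate also carries
    ``references_per_plate`` aliquots of a common reference pool, the
    anchor that plate normalization uses to undo the batch effect.
    """
    rng = np.random.default_rng([config.seed, _STREAM_ENZYMES])
    animals = _animal_ids(config)
    plate_of = {a[0]: i % config.n_plates for i, a in enumerate(animals)}
    rows = []
    for assay in ASSAYS:
        mean = config.enzyme_means[assay]
        ref_true = mean  # reference pool sits at the cohort mean
        for animal_id, *_ in animals:
            plate = plate_of[animal_id]
            eff = config.plate_effects[plate]
            true = mean * rng.lognormal(0.0, config.enzyme_cv)
            nonspec = config.nonspecific_fraction * mean * eff
            total = (true + config.nonspecific_fraction * mean) * eff
            r1 = total * (1 + rng.normal(0, config.duplicate_cv))
            r2 = total * (1 + rng.normal(0, config.duplicate_cv))
            rows.append({"sample_id": animal_id, "plate_id": f"P{plate + 1}",
                         "assay": assay, "rep1": round(r1, 4), "rep2": round(r2, 4),
                         "nonspecific": round(nonspec, 4), "is_reference": False})
        for plate in range(config.n_plates):
            eff = config.plate_effects[plate]
            nonspec = config.nonspecific_fraction * mean * eff
            for j in range(config.references_per_plate):
                total = (ref_true + config.nonspecific_fraction * mean) * eff
                r1 = total * (1 + rng.normal(0, config.duplicate_cv))
                r2 = total * (1 + rng.normal(0, config.duplicate_cv))
                rows.append({"sample_id": f"REF-{assay}-{plate + 1}-{j + 1}",
                             "plate_id": f"P{plate + 1}", "assay": assay,
                             "rep1": round(r1, 4), "rep2": round(r2, 4),
                             "nonspecific": round(nonspec, 4), "is_reference": True})
    return pd.DataFrame(rows)


def simulate_qpcr(config: SyntheticConfig) -> pd.DataFrame:
    """Triplicate Ct wells encoding a target mtDNA copy number.

    For target copy number M the generative identity is
    dCt = log2(M / 2); nuclear Ct is drawn around a fixed anchor,
    mitochondrial Ct is set to nuclear - dCt, and iid noise is added to
    each replicate well. With zero noise ``mtdna_cn`` inverts M exactly.
    """
    rng = np.random.default_rng([config.seed, _STREAM_QPCR])
    rows = []
    for animal_id, gen, cond, _ in _animal_ids(config):
        m = config.qpcr_mtdnacn[(gen, cond)]
        dct = math.log2(m / 2.0)
        ct_n_center = config.qpcr_ct_anchor + rng.normal(0, 0.3)
        ct_mt_center = ct_n_center - dct
        for amplicon, center in (("COX1", ct_mt_center), ("B2M", ct_n_center)):
            cts = center + rng.normal(0, config.qpcr_ct_noise, size=3)
            rows.append({"sample_id": animal_id, "amplicon": amplicon,
                         "ct1": round(float(cts[0]), 4),
                         "ct2": round(float(cts[1]), 4),
                         "ct3": round(float(cts[2]), 4)})
    return pd.DataFrame(rows)


def simulate_ocr(config: SyntheticConfig) -> pd.DataFrame:
    """Phase-plateau OCR traces: plateau mean + iid cycle noise,
    quintuplicate wells per mouse, protein mass drawn positive."""
    rng = np.random.default_rng([config.seed, _STREAM_OCR])
    rows = []
    well = 0
    for (gen, cond), plateaus in config.ocr_plateaus.items():
        for i in range(config.ocr_mice_per_group):
            mouse = f"{gen}-{cond}-{i + 1:03d}"
            for w in range(config.wells_per_mouse):
                well += 1
                protein = max(rng.normal(config.protein_mean_ug,
                                         config.protein_sd_ug), 0.5)
                cycle = 0
                for phase in PHASE_ORDER:
                    for _ in range(config.ocr_cycles_per_phase):
                        cycle += 1
                        ocr = plateaus[phase] + rng.normal(0, config.ocr_noise_sd)
                        rows.append({
                            "well_id": f"W{well:04d}", "mouse_id": mouse,
                            "genotype": gen, "condition": cond,
                            "substrate": "pyruvate_malate", "cycle": cycle,
                            "phase": phase, "ocr": round(float(ocr), 4),
                            "protein_ug": round(float(protein), 4),
                        })
    return pd.DataFrame(rows)


def simulate_all(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """All four inputs keyed by their canonical file stem."""
    return {
        "trials": simulate_trials(config),
        "enzymes": simulate_enzyme_plates(config),
        "qpcr": simulate_qpcr(config),
        "ocr": simulate_ocr(config),
    }
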