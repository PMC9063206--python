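"""Configuration dataclasses for the simulation, cohort and model stages.

All stage configurations are plain dataclasses serializable to/from YAML so a
whole pipeline run is reproducible from one config file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "ConfigurationError",
    "DEFAULT_LAB_PANEL",
    "DEFAULT_COMORBIDITY_PREVALENCES",
    "SyntheticConfig",
    "CohortSpec",
    "NNConfig",
    "PipelineConfig",
    "load_yaml",
    "dump_yaml",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


#: HF-relevant lab analytes with (mean, sd) of the per-measurement value.
#: BUN/creatinine in mg/dL, sodium in mEq/L, NT-proBNP in pg/mL.
DEFAULT_LAB_PANEL: dict[str, tuple[float, float]] = {
    "BUN": (34.4, 24.0),
    "SerumCreatinine": (1.4, 0.6),
    "Sodium": (138.6, 4.6),
    "NTproBNP": (5000.0, 4000.0),
}

#: Baseline per-admission probability of each Elixhauser group in an elderly
#: heart-failure ICU population (plausible magnitudes, not calibrated to any
#: particular registry).  CongestiveHeartFailure is handled separately for
#: cohort-eligible patients (the HF diagnosis itself is always injected).
DEFAULT_COMORBIDITY_PREVALENCES: dict[str, float] = {
    "CongestiveHeartFailure": 0.25,
    "CardiacArrhythmias": 0.35,
    "ValvularDisease": 0.12,
    "PulmonaryCirculation": 0.06,
    "PeripheralVascular": 0.10,
    "HypertensionUncomplicated": 0.45,
    "HypertensionComplicated": 0.10,
    "Paralysis": 0.02,
    "OtherNeurological": 0.06,
    "ChronicPulmonary": 0.25,
    "DiabetesUncomplicated": 0.30,
    "DiabetesComplicated": 0.08,
    "Hypothyroidism": 0.10,
    "RenalFailure": 0.20,
    "LiverDisease": 0.04,
    "PepticUlcer": 0.02,
    "AIDSHIV": 0.005,
    "Lymphoma": 0.01,
    "MetastaticCancer": 0.02,
    "SolidTumor": 0.04,
    "RheumatoidArthritis": 0.03,
    "Coagulopathy": 0.08,
    "Obesity": 0.12,
    "WeightLoss": 0.05,
    "FluidElectrolyte": 0.30,
    "BloodLossAnemia": 0.01,
    "DeficiencyAnemia": 0.15,
    "AlcoholAbuse": 0.05,
    "DrugAbuse": 0.02,
    "Psychoses": 0.03,
    "Depression": 0.10,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic MIMIC-III-shaped EHR generator.

    The latent patient severity is a standard normal draw; ``signal_strength``
    is the log-odds weight linking it to the unplanned 30-day readmission
    probability ``logistic(logit(readmit_base_rate) + signal_strength * z)``.
    The same latent severity shifts lab means (by ``lab_shift`` standard
    deviations per unit severity) and Elixhauser prevalences (by
    ``comorbidity_shift`` probability per unit severity, clipped to [0, 1]),
    so the signal is recoverable from the generated features.
    """

    n_patients: int = 1000
    seed: int = 0
    signal_strength: float = 1.0
    readmit_base_rate: float = 0.235
    mean_admissions_per_patient: float = 3.5
    lab_panel: dict = field(default_factory=lambda: dict(DEFAULT_LAB_PANEL))
    comorbidity_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCES)
    )
    code_vocab_sizes: dict = field(
        default_factory=lambda: {"diagnosis": 300, "procedure": 120, "cpt": 150}
    )
    #: fraction of patients guaranteed >=1 prior admission, >=1 future
    #: admission and an HF ICD-9 code in the index admission.
    eligible_fraction: float = 0.85
    death_rate: float = 0.10
    lab_shift: float = 0.8
    comorbidity_shift: float = 0.12
    mean_lab_measurements: float = 2.5
    calendar_start: str = "2008-01-01"

    def validate(self) -> None:
        if self.n_patients < 10:
            raise ConfigurationError("n_patients must be >= 10")
        if not (0.0 < self.readmit_base_rate < 1.0):
            raise ConfigurationError("readmit_base_rate must lie in (0, 1)")
        if self.signal_strength < 0:
            raise ConfigurationError("signal_strength must be >= 0")
        if self.mean_admissions_per_patient < 2:
            raise ConfigurationError("mean_admissions_per_patient must be >= 2")
        if len(self.lab_panel) != 4:
            raise ConfigurationError("lab_panel must contain exactly 4 analytes")
        for g, p in self.comorbidity_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"prevalence of {g} outside [0, 1]")
        for frac in (self.eligible_fraction, self.death_rate):
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError("fractions must lie in [0, 1]")


#: ICD-9 codes identifying a heart-failure diagnosis; "428" is a family
#: prefix covering all 428.xx codes.
HF_ICD9_EXACT: frozenset[str] = frozenset(
    {"39891", "40201", "40211", "40291", "40401", "40403",
     "40411", "40413", "40491", "40493"}
)
HF_ICD9_PREFIXES: tuple[str, ...] = ("428",)


@dataclass
class CohortSpec:
    """Inclusion/label rules for the heart-failure readmission cohort."""

    hf_exact_codes: frozenset = HF_ICD9_EXACT
    hf_prefix_codes: tuple = HF_ICD9_PREFIXES
    window_days: float = 30.0
    unplanned_types: frozenset = frozenset({"EMERGENCY", "URGENT"})

    def validate(self) -> None:
        if self.window_days <= 0:
            raise ConfigurationError("window_days must be > 0")
        if not (self.hf_exact_codes or self.hf_prefix_codes):
            raise ConfigurationError("HF code set must be non-empty")

    def is_hf_code(self, code: str) -> bool:
        from .severity import normalize_icd9

        norm = normalize_icd9(code)
        return norm in self.hf_exact_codes or any(
            norm.startswith(p) for p in self.hf_prefix_codes
        )


@dataclass
class NNConfig:
    """Hyperparameters of the three-branch neural classifier.

    Hidden widths and learning rate are package defaults; the architecture
    itself (three hidden layers per branch, batch normalization after each
    branch's first hidden layer, 20% dropout after the first, second and
    third hidden layers, one post-concatenation hidden layer, 2-unit
    softmax output) is fixed by ``build_network`` but the layer counts are
    configurable to support the layer-ablation study.
    """

    branch_hidden_sizes: tuple = (128, 64, 32)
    post_concat_size: int = 64
    n_post_concat_layers: int = 1
    dropout_rate: float = 0.20
    epochs: int = 100
    batch_size: int = 10
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if any(w < 1 for w in self.branch_hidden_sizes):
            raise ConfigurationError("branch hidden sizes must be positive")
        if self.n_post_concat_layers < 0:
            raise ConfigurationError("n_post_concat_layers must be >= 0")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (one YAML file drives a run)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    nn: NNConfig = field(default_factory=NNConfig)
    split_ratios: tuple = (0.731, 0.129, 0.140)
    discovery_threshold: int = 1
    n_artificial_clusters: int = 30
    decay_beta: float = 1.0
    include_token_counts: bool = True
    include_marking: bool = True
    normalize_tss: bool = True
    classification_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        self.synthetic.validate()
        self.cohort.validate()
        self.nn.validate()
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ConfigurationError("split_ratios must sum to 1")
        if self.discovery_threshold < 1:
            raise ConfigurationError("discovery_threshold must be >= 1")


def _to_plain(obj):
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def dump_yaml(config, path: str | Path) -> None:
    """Serialize a (possibly nested) config dataclass to YAML."""

    def clean(d):
        if isinstance(d, dict):
            return {k: clean(v) for k, v in d.items()}
        if isinstance(d, (list, tuple, frozenset, set)):
            return [clean(v) for v in _to_plain(d)]
        return d

    Path(path).write_text(yaml.safe_dump(clean(asdict(config)), sort_keys=False))


def load_yaml(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    syn = SyntheticConfig(**raw.pop("synthetic", {}))
    coh_raw = raw.pop("cohort", {})
    if "hf_exact_codes" in coh_raw:
        coh_raw["hf_exact_codes"] = frozenset(coh_raw["hf_exact_codes"])
    if "hf_prefix_codes" in coh_raw:
        coh_raw["hf_prefix_codes"] = tuple(coh_raw["hf_prefix_codes"])
    if "unplanned_types" in coh_raw:
        coh_raw["unplanned_types"] = frozenset(coh_raw["unplanned_types"])
    coh = CohortSpec(**coh_raw)
    nn_raw = raw.pop("nn", {})
    if "branch_hidden_sizes" in nn_raw:
        nn_raw["branch_hidden_sizes"] = tuple(nn_raw["branch_hidden_sizes"])
    nn = NNConfig(**nn_raw)
    if "split_ratios" in raw:
        raw["split_ratios"] = tuple(raw["split_ratios"])
    cfg = PipelineConfig(synthetic=syn, cohort=coh, nn=nn, **raw)
    cfg.validate()
    return cfg
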