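"""Pipeline configuration: validated, serializable, defaults = study setup.

``PipelineConfig`` gathers every tunable of the pipeline into one nested
document (JSON or YAML).  Unknown keys are rejected with a close-match
suggestion; an empty file yields the full default configuration (256-Hz
sampling, 4 harmonics, 1-s windows shifted by 0.05 s, the 6/9/13/18/22-90 Hz
filter bank).
"""

from __future__ import annotations

import difflib
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError as PydanticError

from ssvep_assess.detectors import FilterBankSpec
from ssvep_assess.evaluation import WindowConfig
from ssvep_assess.recording_io import DEFAULT_CHANNELS, PARADIGMS
from ssvep_assess.synthetic_data import (
    DEFAULT_FREQUENCIES,
    StimulusSpec,
    SyntheticConfig,
    TrialTiming,
)


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration keys."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticSection(_Section):
    fs: float = 256.0
    channels: list[str] = list(DEFAULT_CHANNELS)
    n_harmonics: int = 4
    paradigm_gain: dict[str, float] = {
        "OOR": 1.0, "OOS": 1.0, "CBR": 1.0 / 3.0, "CBS": 1.0 / 3.0}
    noise_gamma: float = 1.0
    alpha_amp: float = 0.5
    background_rms: float = 10.0
    target_snr_db: float | None = -11.0


class StimulusSection(_Section):
    frequencies: list[float] = list(DEFAULT_FREQUENCIES)
    paradigms: list[str] = list(PARADIGMS)


class TimingSection(_Section):
    fixation_s: float = 2.0
    target_s: float = 2.0
    preparation_s: float = 1.0
    stimulation_s: float = 5.0
    rest_s: float = 5.0


class PreprocessingSection(_Section):
    band: tuple[float, float] = (0.5, 60.0)
    notch: float | None = 60.0


class FilterBankSection(_Section):
    bands: list[tuple[float, float]] = [
        (6.0, 90.0), (9.0, 90.0), (13.0, 90.0), (18.0, 90.0), (22.0, 90.0)]
    weight_a: float = 1.25
    weight_b: float = 0.25
    order: int = 4
    ripple_db: float = 0.5


class WindowSection(_Section):
    t_win: float = 1.0
    t_shift: float = 0.05
    consecutive_required: int = 3


class PipelineConfig(_Section):
    """Top-level pipeline configuration."""

    synthetic: SyntheticSection = SyntheticSection()
    stimulus: StimulusSection = StimulusSection()
    timing: TimingSection = TimingSection()
    preprocessing: PreprocessingSection = PreprocessingSection()
    filter_bank: FilterBankSection = FilterBankSection()
    window: WindowSection = WindowSection()
    methods: list[str] = ["cca", "fbcca", "mec"]
    trials_per_frequency: int = 8
    output_dir: str = "results"
    seed: int = 0

    # -- conversions to the runtime dataclasses -------------------------

    def synthetic_config(self, seed: int | None = None) -> SyntheticConfig:
        s = self.synthetic
        return SyntheticConfig(
            fs=s.fs, channels=tuple(s.channels), n_harmonics=s.n_harmonics,
            paradigm_gain=dict(s.paradigm_gain), noise_gamma=s.noise_gamma,
            alpha_amp=s.alpha_amp, background_rms=s.background_rms,
            target_snr_db=s.target_snr_db,
            seed=self.seed if seed is None else seed)

    def stimulus_spec(self, paradigm: str = "OOR") -> StimulusSpec:
        return StimulusSpec(paradigm=paradigm,
                            frequencies=tuple(self.stimulus.frequencies),
                            n_targets=len(self.stimulus.frequencies))

    def trial_timing(self) -> TrialTiming:
        t = self.timing
        return TrialTiming(fixation_s=t.fixation_s, target_s=t.target_s,
                           preparation_s=t.preparation_s,
                           stimulation_s=t.stimulation_s, rest_s=t.rest_s)

    def filter_bank_spec(self) -> FilterBankSpec:
        fb = self.filter_bank
        return FilterBankSpec(bands=tuple(tuple(b) for b in fb.bands),
                              weight_a=fb.weight_a, weight_b=fb.weight_b,
                              order=fb.order, ripple_db=fb.ripple_db)

    def window_config(self) -> WindowConfig:
        w = self.window
        return WindowConfig(t_win=w.t_win, t_shift=w.t_shift,
                            consecutive_required=w.consecutive_required)

    def config_hash(self) -> str:
        """Stable short hash of the effective configuration."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _known_keys(model: type[BaseModel]) -> list[str]:
    keys = list(model.model_fields)
    for f in model.model_fields.values():
        ann = f.annotation
        if isinstance(ann, type) and issubclass(ann, BaseModel):
            keys.extend(_known_keys(ann))
    return keys


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a JSON/YAML pipeline configuration.

    ``None`` or an empty file yields all defaults.  Unknown keys raise
    :class:`ConfigError` naming the key and suggesting the closest known
    one.
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    raw: Any = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return PipelineConfig.model_validate(raw)
    except PydanticError as exc:
        messages = []
        known = _known_keys(PipelineConfig)
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            msg = f"{loc}: {err['msg']}"
            if err["type"] == "extra_forbidden":
                bad = str(err["loc"][-1])
                close = difflib.get_close_matches(bad, known, n=1)
                if close:
                    msg += f" (did you mean {close[0]!r}?)"
            messages.append(msg)
        raise ConfigError("invalid configuration: " + "; ".join(messages)) from exc


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialize a configuration (dialect chosen by suffix)."""
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1))
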