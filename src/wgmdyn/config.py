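"""Configuration objects for sensor, kinetic scheme and pipeline runs.

All values are SI (metres, seconds, watts, kelvin); femtometre / picometre /
MW cm⁻² conversions happen only at the presentation layer. Unknown keys are
rejected on load so a typo in a YAML file fails loudly instead of silently
falling back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SensorConfig(_StrictModel):
    """Optical operating point of the plasmon-enhanced WGM sensor.

    Parameters
    ----------
    lambda0 : vacuum resonance wavelength λ0 (m). Default 780 nm (tunable
        diode laser band used with silica microspheres in water).
    P : input light power at the coupler (W).
    S_bar : mean coupling efficiency S̄, the depth of the transmission dip,
        dimensionless in [0, 1).
    dlambda_bar : mean resonance linewidth (FWHM) δλ̄ (m).
    Lambda_ : plasmonic local-intensity enhancement factor Λ of the gold
        nanorod hotspot (dimensionless, ≥ 1; around 800 for the nanorods
        this package models).
    T : temperature (K).
    sample_rate : trace sampling frequency (Hz).
    """

    lambda0: float = Field(default=780e-9, gt=0)
    P: float = Field(default=1e-3, ge=0)
    S_bar: float = Field(default=0.36, ge=0, lt=1)
    dlambda_bar: float = Field(default=0.1e-12, gt=0)
    Lambda_: float = Field(default=800.0, ge=1, alias="Lambda")
    T: float = Field(default=298.15, gt=0)
    sample_rate: float = Field(default=50.0, gt=0)

    model_config = ConfigDict(extra="forbid", validate_assignment=True, populate_by_name=True)


class KineticScheme(_StrictModel):
    """Stochastic description of a simulated single-enzyme trace.

    Turnover events are a renewal process: exponential dwell times between
    events (rate ``event_rate``), exponential event durations (mean
    ``mean_duration``) and truncated-normal positive amplitudes. Permanent
    binding steps, slow drift and Gaussian channel noise complete the trace.

    Defaults emulate the experimental regime this package targets: 3–4 fm
    turnover spikes at a 50 Hz sampling rate, ≈150–180 events per
    measurement, 0.5 fm baseline noise.
    """

    event_rate: float = Field(default=0.5, gt=0)  # s⁻¹, between-event dwell rate
    mean_duration: float = Field(default=0.1, gt=0)  # s, mean event width τ̄
    amp_mean: float = Field(default=3.5e-15, gt=0)  # m
    amp_sd: float = Field(default=0.5e-15, ge=0)  # m
    positive_events: bool = True  # red-shift (positive Δλ) excursions
    binding_step: float = Field(default=0.0)  # m; e.g. 3e-15 (Adk), 5e-15 (3PGK)
    n_binding_steps: int = Field(default=0, ge=0)
    drift_amplitude: float = Field(default=0.0, ge=0)  # m, sinusoid amplitude
    drift_period: float = Field(default=60.0, gt=0)  # s
    drift_walk_sd: float = Field(default=0.0, ge=0)  # m per sample, random walk
    noise_sd: float = Field(default=0.5e-15, ge=0)  # m, Δλ channel
    fwhm_noise_sd: float = Field(default=1e-15, ge=0)  # m, δλ channel

    @model_validator(mode="after")
    def _check_degenerate(self) -> "KineticScheme":
        if self.n_binding_steps > 0 and self.binding_step == 0.0:
            raise ValueError("n_binding_steps > 0 requires a non-zero binding_step")
        return self


class AnalysisConfig(_StrictModel):
    """Detection-stage knobs (Savitzky–Golay window, thresholds)."""

    sg_window_s: float = Field(default=2.0, gt=0)  # detrend window, seconds
    threshold_sigma: float = Field(default=3.0, gt=0)
    fwhm_veto_sigma: float = Field(default=3.0, gt=0)
    min_event_samples: int = Field(default=2, ge=1)
    merge_gap: int = Field(default=1, ge=0)
    step_fraction: float = Field(default=0.10, gt=0, le=1)


class OpticsConfig(_StrictModel):
    """Mode-solver geometry, or a fixed effective mode volume bypassing it."""

    V_eff: Optional[float] = Field(default=None, gt=0)  # m³; bypasses solver if set
    radius: float = Field(default=42.5e-6, gt=0)
    n_sphere: float = Field(default=1.45, gt=1)
    n_medium: float = Field(default=1.33, ge=1)
    polarization: str = Field(default="TE", pattern="^(TE|TM)$")
    radial_order: int = Field(default=1, ge=1)

    @model_validator(mode="after")
    def _check_indices(self) -> "OpticsConfig":
        if self.n_sphere <= self.n_medium:
            raise ValueError("n_sphere must exceed n_medium for a guided mode")
        return self


class EnzymeConfig(_StrictModel):
    """Analyte metadata: name and molecular volume (m³)."""

    name: str = "enzyme"
    molecular_volume: Optional[float] = Field(default=None, gt=0)
    dG_closing: Optional[float] = None  # J mol⁻¹, open→closed ΔG_C (negative)


class RunConfig(_StrictModel):
    """Top-level configuration driving every pipeline stage."""

    sensor: SensorConfig = Field(default_factory=SensorConfig)
    scheme: KineticScheme = Field(default_factory=KineticScheme)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    enzyme: EnzymeConfig = Field(default_factory=EnzymeConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load and validate a YAML (or JSON — YAML superset) config file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
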