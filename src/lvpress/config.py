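"""Validated configuration models for simulation, analysis, and trend aggregation.

All models are pydantic v2 dataclass-style models; ``PipelineConfig`` bundles
them for the command-line interface and can emit a JSON schema for config
files (``PipelineConfig.model_json_schema()``).
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator


class SimConfig(BaseModel):
    """Ground-truth physiological parameters driving the waveform simulator.

    Defaults describe a resting adult rabbit instrumented with an
    intraventricular pressure catheter: heart rate in the low-to-mid 200s bpm,
    systolic pressure ~107 mmHg, end-diastolic pressure ~20 mmHg, and
    contractility/relaxation indices near the middle of the reported
    baseline spans (dP/dt_max ~3000 mmHg/s, Tau66 ~30 ms).
    """

    model_config = ConfigDict(frozen=True)

    heart_rate_bpm: float = Field(240.0, gt=0, lt=600)
    rr_cv: float = Field(0.02, ge=0, le=0.5,
                         description="coefficient of variation of the RR interval")
    lvsp_mmHg: float = Field(107.0, gt=0)
    lvedp_mmHg: float = Field(20.0, gt=0)
    diastolic_floor_mmHg: float = Field(
        14.0, description="asymptote of the relaxation decay; <= LVEDP")
    dpdt_max_mmHg_per_s: float = Field(3000.0, gt=0)
    neg_dpdt_max_mmHg_per_s: float = Field(
        2500.0, gt=0, description="magnitude of the most negative dP/dt")
    tau66_ms: float = Field(30.0, gt=0,
                            description="time from -dP/dt_max to a 66% drop of "
                                        "the systolic-to-diastolic distance")
    noise_sd_mmHg: float = Field(0.5, ge=0)
    drift_amplitude_mmHg: float = Field(3.0, ge=0)
    drift_period_h: float = Field(24.0, gt=0)
    ectopic_rate: float = Field(0.0, ge=0, le=1,
                                description="per-beat probability of a premature beat")
    wall_contact_rate: float = Field(0.0, ge=0,
                                     description="catheter wall-contact events per hour")
    duration_s: float = Field(600.0, gt=0)
    sampling_rate_hz: float = Field(500.0, gt=0)
    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _check_pressure_ordering(self) -> "SimConfig":
        if not (self.diastolic_floor_mmHg <= self.lvedp_mmHg < self.lvsp_mmHg):
            raise ValueError(
                "pressure ordering violated: need diastolic_floor_mmHg <= "
                f"lvedp_mmHg < lvsp_mmHg, got {self.diastolic_floor_mmHg}, "
                f"{self.lvedp_mmHg}, {self.lvsp_mmHg}")
        return self


class AnalysisConfig(BaseModel):
    """Beat detection, derivative estimation, index, and QC settings."""

    model_config = ConfigDict(frozen=True)

    # derivative estimation
    derivative_method: str = Field(
        "auto", pattern="^(auto|central|savgol)$",
        description="'auto' picks central differences on clean signals and a "
                    "Savitzky-Golay derivative when broadband noise is detected")
    savgol_window: int = Field(9, ge=5)
    savgol_polyorder: int = Field(3, ge=2)
    noise_switch_mmHg: float = Field(
        0.1, gt=0, description="robust noise SD above which 'auto' smooths")

    # beat detection
    threshold_frac: float = Field(0.3, gt=0, lt=1,
                                  description="fraction of the rolling dP/dt "
                                              "maximum used as detection threshold")
    rolling_window_s: float = Field(10.0, gt=0)
    refractory_s: float = Field(0.15, gt=0)
    onset_frac: float = Field(0.04, gt=0, lt=1,
                              description="fraction of a beat's dP/dt_max whose "
                                          "upward crossing marks end-diastole")

    # index computation
    vmax_pressure_floor_mmHg: float = Field(1.0, gt=0)
    extremum_band_frac: float = Field(
        0.01, gt=0, lt=0.2,
        description="tolerance band used to refine the earliest attainment of "
                    "a derivative extremum to sub-sample resolution")

    # quality control
    rr_deviation_frac: float = Field(0.25, gt=0)
    rr_context_s: float = Field(30.0, gt=0)
    irregular_max_frac: float = Field(0.05, ge=0, le=1)
    artifact_max_frac: float = Field(0.10, ge=0, le=1)
    pressure_min_mmHg: float = Field(0.0)
    pressure_max_mmHg: float = Field(250.0)
    spike_dpdt_mmHg_per_s: float = Field(
        8000.0, gt=0, description="|dP/dt| above this flags a wall-contact spike")

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        if self.savgol_window % 2 == 0:
            raise ValueError("savgol_window must be odd")
        if self.savgol_polyorder >= self.savgol_window:
            raise ValueError("savgol_polyorder must be < savgol_window")
        if self.pressure_min_mmHg >= self.pressure_max_mmHg:
            raise ValueError("pressure bounds must be increasing")
        return self


class TrendConfig(BaseModel):
    """Epoch and moving-average window lengths."""

    model_config = ConfigDict(frozen=True)

    epoch_s: float = Field(20.0, gt=0)
    window_s: float = Field(3600.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "TrendConfig":
        if self.window_s < self.epoch_s:
            raise ValueError("window_s must be >= epoch_s")
        return self


class PipelineConfig(BaseModel):
    """Top-level configuration consumed by the CLI subcommands."""

    model_config = ConfigDict(frozen=True)

    sim: SimConfig = SimConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    trend: TrendConfig = TrendConfig()
    seed: int = Field(0, ge=0)
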