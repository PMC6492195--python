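"""Pipeline configuration: a YAML-serializable nested dataclass schema."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml


@dataclass
class AcquisitionConfig:
    lines_per_interleaf: int = 28  # 104 ms window / 3.7 ms TR
    tr: float = 0.0037  # s
    rr_mean: float = 1.0  # s
    rr_jitter: float = 0.03  # s
    noise_sd: float = 0.01  # complex noise SD per k-space sample
    n_coils: int = 6

    def validate(self) -> None:
        if self.lines_per_interleaf < 1 or self.n_coils < 1:
            raise ValueError("lines_per_interleaf and n_coils must be >= 1")
        if self.tr <= 0 or self.rr_mean <= 0 or self.rr_jitter < 0 or self.noise_sd < 0:
            raise ValueError("invalid acquisition timing/noise values")


@dataclass
class BinningConfig:
    n_bins: int = 4
    alpha: float = 1.0  # soft-weight decay per bin width
    reject_n_sd: float = 2.0

    def validate(self) -> None:
        if self.n_bins < 1 or self.alpha < 0 or self.reject_n_sd <= 0:
            raise ValueError("invalid binning configuration")


@dataclass
class ReconSettings:
    max_iter: int = 30
    tol: float = 1e-6
    use_soft_weights_mc: bool = False

    def validate(self) -> None:
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("invalid reconstruction settings")


@dataclass
class PETConfig:
    n_angles: int = 84
    mean_counts: float = 4.0e6
    randoms_fraction: float = 0.1
    scatter_fraction: float = 0.1
    n_iter: int = 3
    n_subsets: int = 21
    n_substeps: int = 8

    def validate(self) -> None:
        if self.n_angles < 8 or self.mean_counts <= 0:
            raise ValueError("invalid PET geometry/counts")
        if not (0 <= self.randoms_fraction and 0 <= self.scatter_fraction):
            raise ValueError("fractions must be >= 0")
        if self.randoms_fraction + self.scatter_fraction >= 1:
            raise ValueError("randoms + scatter fractions must be < 1")
        if self.n_angles % self.n_subsets != 0:
            raise ValueError("n_subsets must divide n_angles")


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, reproducible from the seed."""

    seed: int = 0
    grid_shape: Tuple[int, int] = (96, 96)
    spacing: Tuple[float, float] = (1.0, 1.0)
    resp_amp_fh: float = 8.0
    resp_amp_rl: float = 2.0
    contraction_fraction: float = 0.35
    deep_breath_prob: float = 0.05
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    binning: BinningConfig = field(default_factory=BinningConfig)
    recon: ReconSettings = field(default_factory=ReconSettings)
    pet: PETConfig = field(default_factory=PETConfig)
    motion_source: str = "estimated"  # estimated | ground_truth
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if self.motion_source not in ("estimated", "ground_truth"):
            raise ValueError("motion_source must be 'estimated' or 'ground_truth'")
        self.acquisition.validate()
        self.binning.validate()
        self.recon.validate()
        self.pet.validate()

    # -- YAML round-trip ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["spacing"] = list(self.spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("acquisition", AcquisitionConfig),
            ("binning", BinningConfig),
            ("recon", ReconSettings),
            ("pet", PETConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "spacing" in d:
            d["spacing"] = tuple(d["spacing"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
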