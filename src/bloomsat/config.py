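"""Run configuration: every tunable threshold of the pipeline, with defaults.

Configs round-trip through a flat ``key = value`` text file so a run can be
reproduced from its manifest alone.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

__all__ = ["RunConfig"]

_BOOL_TRUE = {"true", "1", "yes", "on"}
_BOOL_FALSE = {"false", "0", "no", "off"}


@dataclass
class RunConfig:
    """All pipeline tunables.

    ``nu``/``gamma`` are the one-class SVM parameters (``gamma_date2``
    optionally overrides ``gamma`` for the second date — the kernel width is
    scene-dependent). ``train_quantile`` is the fraction of scene pixels,
    ranked by flower-likeness, used as the one-class training sample.
    ``fraction_pure``/``fraction_mixed_low``/``angle_max`` define the joint
    abundance/angle region rule. ``n_classes`` is the ISODATA class count;
    ``merge_radius`` the centroid buffer-merge radius and
    ``match_tolerance`` the cross-date matching distance (both meters).
    """

    nu: float = 0.1
    gamma: float = 0.1
    gamma_date2: float | None = None
    train_quantile: float = 0.001
    fraction_pure: float = 0.80
    fraction_mixed_low: float = 0.25
    angle_max: float = 0.05
    angle_applies_to_pure: bool = False
    n_classes: int = 25
    isodata_max_iter: int = 100
    merge_radius: float = 5.0
    match_tolerance: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nu <= 1:
            raise ValueError("nu must lie in (0, 1]")
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if self.gamma_date2 is not None and not self.gamma_date2 > 0:
            raise ValueError("gamma_date2 must be > 0")
        if not 0 < self.train_quantile <= 1:
            raise ValueError("train_quantile must lie in (0, 1]")
        if not 0 < self.fraction_mixed_low < self.fraction_pure <= 1:
            raise ValueError("need 0 < fraction_mixed_low < fraction_pure <= 1")
        if not self.angle_max > 0:
            raise ValueError("angle_max must be > 0")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.merge_radius < 0 or self.match_tolerance < 0:
            raise ValueError("radii must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# bloomsat run configuration\n")
            for key, value in self.to_dict().items():
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        raw: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                raw[key] = value
        kwargs = {}
        for key, value in raw.items():
            kwargs[key] = _parse_value(key, value)
        return cls(**kwargs)


def _parse_value(key: str, value: str):
    low = value.lower()
    if low in ("none", ""):
        return None
    if low in _BOOL_TRUE:
        return True
    if low in _BOOL_FALSE:
        return False
    try:
        if any(c in value for c in ".eE") and key != "seed":
            return float(value)
        return int(value)
    except ValueError:
        try:
            return float(value)
        except ValueError:
            return value
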