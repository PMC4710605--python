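"""Run configuration: similarity threshold, gate rule sets, promiscuity
alerts.  YAML-loadable, and always echoed verbatim into outputs so a
report is interpretable without the invocation that produced it."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .descriptors import BBBRules, Ro5Thresholds
from .errors import ConfigError
from .triage import DEFAULT_ALERTS, compile_alerts


@dataclass
class RunConfig:
    threshold: float = 0.75
    ro5: Ro5Thresholds = field(default_factory=Ro5Thresholds)
    bbb_rules: BBBRules = field(default_factory=BBBRules)
    demote_promiscuous: bool = False
    seed: int | None = None
    alerts: tuple[tuple[str, str], ...] = DEFAULT_ALERTS

    def __post_init__(self):
        if not (0.0 < self.threshold <= 1.0):
            raise ConfigError(f"threshold must lie in (0, 1], got {self.threshold}")
        compile_alerts(self.alerts)  # fail fast on malformed SMARTS

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "ro5": self.ro5.to_dict(),
            "bbb_rules": self.bbb_rules.to_dict(),
            "demote_promiscuous": self.demote_promiscuous,
            "seed": self.seed,
            "alerts": [list(a) for a in self.alerts],
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs: dict = {}
        if "threshold" in data:
            kwargs["threshold"] = float(data["threshold"])
        if "ro5" in data:
            kwargs["ro5"] = Ro5Thresholds(**data["ro5"])
        if "bbb_rules" in data:
            kwargs["bbb_rules"] = BBBRules(**data["bbb_rules"])
        if "demote_promiscuous" in data:
            kwargs["demote_promiscuous"] = bool(data["demote_promiscuous"])
        if "seed" in data and data["seed"] is not None:
            kwargs["seed"] = int(data["seed"])
        if "alerts" in data:
            kwargs["alerts"] = tuple((str(n), str(s)) for n, s in data["alerts"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
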