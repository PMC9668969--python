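"""Run configuration: one object echoed verbatim into every output artifact."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from lipidflux.constants import DEFAULT_TEMPERATURE
from lipidflux.errors import DataError


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    t_eval: float = 0.002
    fit_window: tuple[float, float] = (0.0, 0.1)
    n_lambda_windows: int = 120
    elec_start: float = 0.25
    bulk_reference: str = "2:1:1"
    output_dir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                raw = yaml.safe_load(fh)
            else:
                raw = json.load(fh)
        if not isinstance(raw, dict):
            raise DataError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"{path}: unknown config keys {sorted(unknown)}")
        if "fit_window" in raw:
            raw["fit_window"] = tuple(raw["fit_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit_window"] = list(d["fit_window"])
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
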