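"""Layered run configuration: defaults < config file < explicit overrides.

The config file dialect is deliberately tiny: flat dotted keys, one
``key = value`` assignment per line, ``#`` comments.  Unknown keys are an
error (with a closest-match suggestion), and every value is validated
against its module's preconditions before any computation starts.  The
fully resolved configuration can be serialized back out, so each output
directory carries a provenance copy.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, fields

from .pipeline import METHODS

__all__ = ["RunConfig", "load_config", "parse_config_file"]


@dataclass
class RunConfig:
    method: str = "wfcm"
    wavelet_family: str = "db4"
    wavelet_levels: int = 1
    wavelet_mode: str = "approximation"
    wavelet_magnitude_sqrt: bool = False
    wavelet_extension: str = "symmetric"
    cluster_c: int = 3
    cluster_fuzziness: float = 2.0
    cluster_tol: float = 1e-5
    cluster_max_iter: int = 300
    cluster_seed: int = 0
    preselect_rulebase_path: str = ""
    srm_q: int = 256
    srm_predicate: str = "canonical"
    lesion_polarity: str = "dark"
    threshold: float = 0.5
    seed: int = 0
    log_level: str = "info"

    def validate(self) -> "RunConfig":
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.wavelet_levels < 1:
            raise ValueError("wavelet.levels must be >= 1")
        if self.wavelet_mode not in ("approximation", "magnitude"):
            raise ValueError("wavelet.mode must be 'approximation' or 'magnitude'")
        if self.cluster_c < 1:
            raise ValueError("cluster.C must be >= 1")
        if self.cluster_fuzziness <= 1:
            raise ValueError("cluster.fuzziness must be > 1")
        if self.cluster_tol <= 0 or self.cluster_max_iter < 1:
            raise ValueError("cluster.tol must be > 0 and cluster.max_iter >= 1")
        if self.srm_q < 1:
            raise ValueError("srm.Q must be >= 1")
        if self.srm_predicate not in ("canonical", "as_printed"):
            raise ValueError("srm.predicate must be 'canonical' or 'as_printed'")
        if self.lesion_polarity not in ("dark", "light"):
            raise ValueError("lesion.polarity must be 'dark' or 'light'")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be a nonnegative 31-bit integer")
        return self

    def dumps(self) -> str:
        lines = [f"{_FIELD_TO_KEY[f.name]} = {getattr(self, f.name)}" for f in fields(self)]
        return "\n".join(lines) + "\n"


#: dotted config key <-> dataclass field
_KEY_TO_FIELD = {
    "method": "method",
    "wavelet.family": "wavelet_family",
    "wavelet.levels": "wavelet_levels",
    "wavelet.mode": "wavelet_mode",
    "wavelet.magnitude_sqrt": "wavelet_magnitude_sqrt",
    "wavelet.extension": "wavelet_extension",
    "cluster.C": "cluster_c",
    "cluster.fuzziness": "cluster_fuzziness",
    "cluster.tol": "cluster_tol",
    "cluster.max_iter": "cluster_max_iter",
    "cluster.seed": "cluster_seed",
    "preselect.rulebase_path": "preselect_rulebase_path",
    "srm.Q": "srm_q",
    "srm.predicate": "srm_predicate",
    "lesion.polarity": "lesion_polarity",
    "threshold": "threshold",
    "seed": "seed",
    "log_level": "log_level",
}
_FIELD_TO_KEY = {v: k for k, v in _KEY_TO_FIELD.items()}


def _coerce(field_name: str, value: str):
    kind = RunConfig.__dataclass_fields__[field_name].type
    raw = value.strip()
    if kind == "bool":
        if raw.lower() in ("true", "1", "yes", "on"):
            return True
        if raw.lower() in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"cannot parse {raw!r} as a boolean")
    if kind == "int":
        return int(raw)
    if kind == "float":
        return float(raw)
    return raw


def parse_config_file(path: str) -> dict[str, object]:
    """Read a flat dotted-key config file into a field dict."""
    out: dict[str, object] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in _KEY_TO_FIELD:
                hint = difflib.get_close_matches(key, _KEY_TO_FIELD, n=1)
                suffix = f"; did you mean {hint[0]!r}?" if hint else ""
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}{suffix}")
            field_name = _KEY_TO_FIELD[key]
            out[field_name] = _coerce(field_name, value)
    return out


def load_config(path: str | None = None, overrides: dict[str, object] | None = None) -> RunConfig:
    """Resolve a configuration with precedence overrides > file > defaults.

    ``overrides`` maps dotted keys or field names to values (``None`` values
    are ignored, so unset CLI flags fall through to the file/defaults).
    """
    values: dict[str, object] = {}
    if path:
        values.update(parse_config_file(path))
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        field_name = _KEY_TO_FIELD.get(key, key)
        if field_name not in RunConfig.__dataclass_fields__:
            hint = difflib.get_close_matches(key, _KEY_TO_FIELD, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suffix}")
        values[field_name] = value
    return RunConfig(**values).validate()
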