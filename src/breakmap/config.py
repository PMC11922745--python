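"""Plain-text key=value configuration and logging setup.

Config files are flat ``key = value`` lines; ``#`` starts a comment. Values
are parsed as int, then float, then bare string; comma-separated values
become lists. Every stochastic operation takes an explicit integer seed,
which is echoed in logs and output headers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

log = logging.getLogger("breakmap")


def _parse_value(raw: str) -> Any:
    raw = raw.strip()
    if "," in raw:
        return [_parse_value(v) for v in raw.split(",")]
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    return raw


def read_config(path: str | Path) -> dict[str, Any]:
    """Read a flat key=value config file."""
    out: dict[str, Any] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = line.split("=", 1)
            out[key.strip()] = _parse_value(raw)
    return out


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )


def header_comment(**params: Any) -> str:
    """Commented TSV header line echoing parameters (units, seed, ...)."""
    body = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# breakmap {body}\n"
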