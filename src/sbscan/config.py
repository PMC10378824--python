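"""Run configuration: flat ``key = value`` text with an optional [motifs]
section (one ``name pattern max_mismatch`` per line).  Unknown keys are
rejected so typos fail loudly."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .motif_scan import DegenerateMotif, default_panel

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # ORF prediction
    orf_min_nt: int = 75
    orf_min_aa: int = 95
    orf_starts: tuple[str, ...] = ("ATG", "GTG", "TTG")
    # iteron-like tandem repeats
    itr_unit_range: tuple[int, int] = (15, 30)
    itr_min_copies: int = 2
    itr_max_mismatch: int = 3
    # AT-rich detection
    at_window: int = 20
    at_gc_max: float = 0.30
    at_min_len: int = 40
    # classifier thresholds
    g1_rep_aa: tuple[int, int] = (270, 332)
    g2_rep_aa: tuple[int, int] = (333, 460)
    small_orf_aa: tuple[int, int] = (90, 160)
    # misc
    seed: int = 0
    motifs: list[DegenerateMotif] = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        for name in ("orf_min_nt", "orf_min_aa", "itr_min_copies", "at_window", "at_min_len"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.itr_max_mismatch < 0 or not (0 < self.at_gc_max < 1):
            raise ConfigError("itr_max_mismatch must be >= 0 and at_gc_max in (0, 1)")


_INT_PAIRS = {"itr_unit_range", "g1_rep_aa", "g2_rep_aa", "small_orf_aa"}
_INTS = {"orf_min_nt", "orf_min_aa", "itr_min_copies", "itr_max_mismatch",
         "at_window", "at_min_len", "seed"}
_FLOATS = {"at_gc_max"}


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat key=value config file with an optional [motifs] section."""
    kwargs: dict = {}
    motifs: list[DegenerateMotif] | None = None
    section = None
    known = {f.name for f in fields(RunConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section != "motifs":
                raise ConfigError(f"line {lineno}: unknown section [{section}]")
            motifs = []
            continue
        if section == "motifs":
            parts = line.split()
            if len(parts) != 3:
                raise ConfigError(
                    f"line {lineno}: motif lines are 'name pattern max_mismatch'"
                )
            try:
                motifs.append(DegenerateMotif(parts[0], parts[1], int(parts[2])))
            except ValueError as e:
                raise ConfigError(f"line {lineno}: {e}") from e
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in known or key == "motifs":
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
        try:
            if key in _INTS:
                kwargs[key] = int(value)
            elif key in _FLOATS:
                kwargs[key] = float(value)
            elif key in _INT_PAIRS:
                a, b = value.replace(",", " ").split()
                kwargs[key] = (int(a), int(b))
            elif key == "orf_starts":
                kwargs[key] = tuple(
                    c.strip().upper() for c in value.split(",") if c.strip()
                )
            else:  # pragma: no cover - all keys typed above
                raise ConfigError(f"line {lineno}: unhandled key {key!r}")
        except ConfigError:
            raise
        except Exception as e:
            raise ConfigError(f"line {lineno}: bad value for {key!r}: {value!r}") from e
    if motifs is not None:
        kwargs["motifs"] = motifs
    return RunConfig(**kwargs)
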