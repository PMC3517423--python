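"""Analysis configuration: every tunable constant, file- and flag-overridable.

Precedence: built-in defaults < YAML config file < command-line flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """All scan parameters in one place.

    The promoter cutoff is carried as a configurable default, not a
    calibrated constant: published two-box searches rarely state the
    scale their score lives on.
    """

    consensus_core: str = "TACTGTGAC"
    consensus_pattern: str = "TACTRTGMC"
    cut_offset: int = 4
    spacer_min: int = 16
    spacer_max: int = 19
    promoter_cutoff: float = 5.31
    promoter_pseudocount: float = 0.5
    terminase_core: str = "GATATCCC"
    left_cut_overhang: int = 4
    right_cut_overhang: int = 0
    dtr_min_len: int = 20
    junction_flank: int = 10
    term_min_stem: int = 5
    term_max_stem: int = 15
    term_min_loop: int = 3
    term_max_loop: int = 10
    term_max_mismatch: int = 1
    term_min_u_run: int = 3
    term_u_window: int = 8
    compare_tolerance: float = 2.0
    orf_min_len: int = 90
    seed: int = 0

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "AnalysisConfig":
        """Defaults, updated from a YAML file, then from keyword overrides.

        Overrides with value None are ignored (unset flags).
        """
        cfg = cls()
        known = {f.name for f in fields(cls)}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
            unknown = set(data) - known
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            cfg = replace(cfg, **data)
        clean = {k: v for k, v in overrides.items() if v is not None}
        unknown = set(clean) - known
        if unknown:
            raise ValueError(f"unknown config overrides: {sorted(unknown)}")
        return replace(cfg, **clean)

    def digest(self) -> str:
        import hashlib
        import json
        from dataclasses import asdict

        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]
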