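"""Design constraints and configuration loading.

Defaults reflect common PCR-RFLP practice: 18-26 nt primers, a 100-500 nt
product (small enough for robust amplification, large enough to resolve
fragments on agarose), 20-80% GC, and at most 5 degC of Tm imbalance
between the two primers of a pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class DesignConstraints:
    primer_len_min: int = 18
    primer_len_max: int = 26
    product_min: int = 100
    product_max: int = 500
    gc_min: float = 20.0
    gc_max: float = 80.0
    max_tm_difference: float = 5.0
    na_molar: float = 0.05  # monovalent cation concentration for the Tm formula
    mismatch_window: int = 5  # mutagenic mismatch must sit within this many nt of the 3' end
    mining_window: int = 30  # nt each side of the variant scanned for discriminating sites
    mutagenic_strands: str = "forward"  # "forward" or "both"
    max_pairs: int = 10
    max_designs: int = 10

    def __post_init__(self) -> None:
        if self.primer_len_min < 1 or self.primer_len_max < self.primer_len_min:
            raise ValueError("invalid primer length range")
        if self.product_min < 1 or self.product_max < self.product_min:
            raise ValueError("invalid product length range")
        if self.mutagenic_strands not in ("forward", "both"):
            raise ValueError("mutagenic_strands must be 'forward' or 'both'")
        if self.mismatch_window < 1:
            raise ValueError("mismatch window must be >= 1")

    @property
    def product_midpoint(self) -> float:
        return (self.product_min + self.product_max) / 2

    def with_overrides(self, **kwargs) -> "DesignConstraints":
        return replace(self, **kwargs)


def load_constraints(path: str | Path) -> DesignConstraints:
    """Read a YAML or JSON constraint block; unknown keys are an error."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    if data is None:
        return DesignConstraints()
    known = {f.name for f in fields(DesignConstraints)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown constraint keys: {sorted(unknown)}")
    return DesignConstraints(**data)
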