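"""Run configuration: validated defaults, YAML loading, config hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .scanner import DEFAULT_PAM, DEFAULT_PROTOSPACER_LEN, DEFAULT_WINDOW, IUPAC


@dataclass(frozen=True)
class RunConfig:
    pam_pattern: str = DEFAULT_PAM
    protospacer_len: int = DEFAULT_PROTOSPACER_LEN
    window: tuple[int, int] = DEFAULT_WINDOW
    alphabet: tuple[str, ...] = ("T",)
    max_multiplicity: int = 1
    flank: int = 23  # nt of genomic flank used on each side, when available
    upstream_flank_len: int = 0  # flank split of a single genomic FASTA record
    downstream_flank_len: int = 0
    overhang_forward_5: str = ""
    overhang_forward_3: str = ""
    overhang_reverse_5: str = ""
    overhang_reverse_3: str = ""
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    min_overlap: int = 30
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self):
        for sym in self.pam_pattern:
            if sym not in IUPAC:
                raise ValueError(f"invalid IUPAC symbol {sym!r} in PAM pattern")
        if self.protospacer_len < 1:
            raise ValueError("protospacer_len must be >= 1")
        lo, hi = self.window
        if not (-self.protospacer_len <= lo <= hi <= -1):
            raise ValueError(f"window {self.window} invalid for protospacer length")
        if not self.alphabet or set(self.alphabet) - {"T", "G", "A"}:
            raise ValueError("alphabet must be a non-empty subset of {T, G, A}")
        if self.max_multiplicity < 1:
            raise ValueError("max_multiplicity must be >= 1")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Config file overrides defaults; keyword overrides beat the file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window", "alphabet"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window)
        d["alphabet"] = list(self.alphabet)
        return d

    def digest(self) -> str:
        """Short stable hash of the configuration, echoed into output headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
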