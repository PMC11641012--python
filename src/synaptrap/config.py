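"""Run configuration: every analysis knob with a documented default.

The configuration is serialised verbatim (key = value) into run reports
together with a content hash, so results are reproducible from
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from synaptrap.io import parse_keyvalue, write_keyvalue
from synaptrap.polymer import ConstructState, ThermalContext, tether_states

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Analysis parameters with defaults matching the study conditions."""

    # construct geometry
    handle_bp: int = 5000               # total dsDNA handle length
    spacer_nt: int = 114                # ssDNA released on disassembly
    hairpin_nt: tuple = (63, 63)        # nucleotides per hairpin
    synapse_offset_nm: float = 10.5     # end-to-end of the assembled complex
    hairpin_offset_nm: float = 2.0      # end-to-end of one folded hairpin
    delta_L_sub_nm: float = 44.6        # synapse -> substate contour change

    # polymer parameters
    kBT_pN_nm: float = 4.11             # ~298 K
    ds_persistence_nm: float = 45.0
    ds_stretch_modulus_pN: float = 1200.0
    ss_persistence_nm: float = 2.0
    ss_rise_nm_per_nt: float = 0.68
    ds_rise_nm_per_bp: float = 0.34

    # preprocessing / detection
    downsample_factor: int = 1          # generated data is already at 260 Hz
    crosstalk: float = 0.0
    min_peak_force_pN: float = 30.0     # cycles below this are excluded
    min_drop_pN: float = 1.0
    min_jump_nm: float = 2.0
    detector_window: int = 5
    smooth_window: int = 5
    min_fit_force_pN: float = 2.0
    residual_threshold_nm: float = 15.0

    # fingerprinting / classification
    fingerprint_nm: float = 71.0
    fingerprint_tol_nm: float = 10.0
    unbind_threshold_pN: float = 6.0

    seed: int = 0

    def thermal(self) -> ThermalContext:
        return ThermalContext(self.kBT_pN_nm)

    def states(self) -> dict[str, ConstructState]:
        return tether_states(
            handle_bp=self.handle_bp, spacer_nt=self.spacer_nt,
            hairpin_nt=tuple(self.hairpin_nt),
            synapse_offset_nm=self.synapse_offset_nm,
            hairpin_offset_nm=self.hairpin_offset_nm,
            delta_L_sub_nm=self.delta_L_sub_nm,
            ds_persistence_nm=self.ds_persistence_nm,
            ds_stretch_modulus_pN=self.ds_stretch_modulus_pN,
            ss_persistence_nm=self.ss_persistence_nm,
            ss_rise_nm_per_nt=self.ss_rise_nm_per_nt,
            ds_rise_nm_per_bp=self.ds_rise_nm_per_bp)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_file(self, path) -> None:
        write_keyvalue(self.to_dict(), path)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        raw = parse_keyvalue(path)
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "hairpin_nt" in raw and not isinstance(raw["hairpin_nt"], tuple):
            raw["hairpin_nt"] = (raw["hairpin_nt"],)
        return cls(**raw)
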