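"""Run configuration: a single serializable mapping that reproduces a run.

A RunConfig bundles the system source (toy preset or PDB + charge table),
the CV groups, every sampler parameter and the analysis thresholds; a run
archives its config next to its outputs so that config + seed reproduce the
trajectory bit-identically on one platform.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .model import ReTAMDParams

__all__ = ["RunConfig", "PRESETS", "preset_config"]


#: Named enhanced-sampling presets mirroring the published parameter sets:
#: (c, k, h) = (0.02, 40, 10) for the 13-mer, (0.02, 30, 10) for the 7-mer,
#: (0.7, 30, 10) for the 3-mer, with 3/2/1 CV groups respectively.  The
#: dynamics entries (dt, gamma_bar, masses) are the toy-model defaults.
PRESETS = {
    "pt13": dict(ligand_length=13, c_ratchet=0.02, k_adapt=40.0, h_adapt=10.0),
    "pt7": dict(ligand_length=7, c_ratchet=0.02, k_adapt=30.0, h_adapt=10.0),
    "pt3": dict(ligand_length=3, c_ratchet=0.7, k_adapt=30.0, h_adapt=10.0),
}

#: Toy CG-complex dynamics defaults (see docs/methods.md for rationale).
TOY_DYNAMICS = dict(
    kappa=100.0, gamma=0.5, beta_inv=0.6, gamma_bar=2.0, dt=0.005,
    n_steps=10_000, frame_stride=50,
)


@dataclass
class RunConfig:
    system: dict = field(default_factory=lambda: {
        "kind": "toy", "n_receptor": 210, "ligand_length": 13, "seed": 0})
    params: ReTAMDParams = field(default_factory=ReTAMDParams)
    cv_groups: list | None = None       # None → preset groups from generator
    analysis: dict = field(default_factory=lambda: {
        "cutoff": 4.0, "charge_threshold": 0.2,
        "contact_level": 0.5, "hotspot_level": 0.8})
    out_dir: str = "retamd_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        params = d.get("params", {})
        if isinstance(params, dict):
            d["params"] = ReTAMDParams(**params)
        return cls(**d)

    def save(self, path) -> str:
        with open(str(path), "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return str(path)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(str(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def preset_config(name: str, seed: int = 0, n_steps: int | None = None) -> RunConfig:
    """A ready-to-run toy configuration for one of the named presets."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[name]
    params = ReTAMDParams(
        **TOY_DYNAMICS,
        k_adapt=p["k_adapt"], h_adapt=p["h_adapt"], c_ratchet=p["c_ratchet"],
        seed=seed,
    )
    if n_steps is not None:
        params.n_steps = n_steps
    return RunConfig(
        system={"kind": "toy", "n_receptor": 210,
                "ligand_length": p["ligand_length"], "seed": seed},
        params=params,
        out_dir=f"retamd_{name}",
    )
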