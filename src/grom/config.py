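"""Run configuration: TOML parsing, defaults and provenance hashing.

A :class:`RunConfig` aggregates every tunable of the pipeline — cohort
generation, registration, model parameters, transfer and reduction options —
so that any experiment is reproducible from (config, master_seed) alone.
Every artifact written by the CLI embeds ``config_hash`` for traceability.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

from .cohort import CohortSpec
from .imaging import RegistrationOptions
from .models import ModelAParams, ModelBParams


@dataclass
class TransferOptions:
    k_neighbors: int = 8
    sigma_factor: float = 1.0


@dataclass
class RomOptions:
    d_list: tuple[int, ...] = (2, 5, 10, 20, 30)
    mass_weighted: bool = False


@dataclass
class RunConfig:
    cohort: CohortSpec = dataclass_field(
        default_factory=lambda: CohortSpec(n_healthy=28, n_inph=12))
    registration: RegistrationOptions = dataclass_field(
        default_factory=RegistrationOptions)
    model_a: ModelAParams = dataclass_field(default_factory=ModelAParams)
    model_b: ModelBParams = dataclass_field(default_factory=ModelBParams)
    transfer: TransferOptions = dataclass_field(default_factory=TransferOptions)
    rom: RomOptions = dataclass_field(default_factory=RomOptions)
    backend: str = "analytic"            # "analytic" | "demons"

    @property
    def master_seed(self) -> int:
        return self.cohort.master_seed

    def model_params(self, which: str):
        return self.model_a if which.upper() == "A" else self.model_b

    def to_dict(self) -> dict:
        def plain(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {k: plain(getattr(obj, k))
                        for k in obj.__dataclass_fields__}
            if isinstance(obj, dict):
                return {"|".join(k) if isinstance(k, tuple) else k: plain(v)
                        for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if hasattr(obj, "tolist"):
                return obj.tolist()
            return obj

        return plain(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _apply(obj, section: dict, name: str):
    for k, v in section.items():
        if not hasattr(obj, k):
            raise KeyError(f"unknown key {k!r} in [{name}]")
        if isinstance(getattr(obj, k), tuple) and isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        setattr(obj, k, v)
    if hasattr(obj, "__post_init__"):
        obj.__post_init__()
    return obj


def load_config(path: str | Path | None = None,
                seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a TOML file (all sections optional).

    Recognized sections: [cohort], [registration], [model_a], [model_b]
    (omega keys written as "a,c" pairs), [transfer], [rom]; top-level key
    ``backend``.  ``seed`` overrides the cohort master_seed.
    """
    cfg = RunConfig()
    if path is not None:
        doc = tomllib.loads(Path(path).read_text())
        if "cohort" in doc:
            sec = dict(doc["cohort"])
            if "image_shape" in sec:
                sec["image_shape"] = tuple(sec["image_shape"])
            _apply(cfg.cohort, sec, "cohort")
        if "registration" in doc:
            sec = dict(doc["registration"])
            for k in ("levels", "iterations"):
                if k in sec:
                    sec[k] = tuple(sec[k])
            _apply(cfg.registration, sec, "registration")
        if "model_a" in doc:
            _apply(cfg.model_a, doc["model_a"], "model_a")
        if "model_b" in doc:
            sec = dict(doc["model_b"])
            if "omega" in sec:
                sec["omega"] = {tuple(k.split(",")): v
                                for k, v in sec["omega"].items()}
            _apply(cfg.model_b, sec, "model_b")
        if "transfer" in doc:
            _apply(cfg.transfer, doc["transfer"], "transfer")
        if "rom" in doc:
            sec = dict(doc["rom"])
            if "d_list" in sec:
                sec["d_list"] = tuple(sec["d_list"])
            _apply(cfg.rom, sec, "rom")
        if "backend" in doc:
            cfg.backend = doc["backend"]
            if cfg.backend not in ("analytic", "demons"):
                raise ValueError("backend must be 'analytic' or 'demons'")
    if seed is not None:
        cfg.cohort.master_seed = int(seed)
    return cfg


DEFAULT_CONFIG_TOML = """\
# grom run configuration (all values shown are the defaults)
backend = "analytic"        # deformation backend: "analytic" | "demons"

[cohort]
n_healthy = 28
n_inph = 12
master_seed = 1
image_shape = [192, 192]    # voxels
voxel_size = 1.0            # mm
mesh_h = 1.5                # mm

[registration]              # demons backend settings (voxel units)
levels = [4, 2, 1]
iterations = [100, 100, 100]
sigma_update = 1.0
sigma_total = 1.5
max_step = 0.5

[model_a]                   # two-compartment tracer transport (mm-s units)
n_e = 0.2                   # ECS volume fraction
n_p = 0.02                  # PVS volume fraction
D_e = 1.3e-4                # mm^2/s
D_p = 3.9e-4                # mm^2/s
pi_ep = 2.9e-2              # 1/s
pi_pb = 2.0e-8              # 1/s
k_e = 1.0e-5                # mm/s
k_p = 3.7e-4                # mm/s
a_pial = 0.52               # mm^2/s
a_ventricle = 0.2           # mm^2/s
phi_vf = 0.2
tau1 = 4.43e4               # s
tau2 = 8.5e4                # s
t_eval = 60120.0            # s (= 16.7 h)

[model_b]                   # steady 7-network MPET (mm-s-Pa units)
B_in = 20.0                 # mm^2/s  NOT-FROM-TABLES: override for quantitative use
Q_prod = 5.5                # mm^3/s  (0.33 ml/min)
p_DS = 1119.9               # Pa      (8.4 mmHg)
p_CSF = 1333.22             # Pa      NOT-FROM-TABLES (10 mmHg)
beta1 = 1e-3
beta2 = 1e-3
beta3 = 1e-7

[transfer]
k_neighbors = 8
sigma_factor = 1.0

[rom]
d_list = [2, 5, 10, 20, 30]
mass_weighted = false
"""
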