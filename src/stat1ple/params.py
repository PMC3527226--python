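"""Parameter container for the IFNγ → STAT1 pathway model.

All kinetic constants carry units of 1/min (or 1/(min·a.u.) where a second
species enters the mass-action product), delays are in minutes, and
concentrations are in arbitrary units (a.u.) because the immunoblot data the
model is calibrated against are only defined up to a multiplicative scaling
factor per observable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import yaml

__all__ = ["PathwayParameters", "consistent_initial_stat1"]


@dataclass(frozen=True)
class PathwayParameters:
    """Rate constants, delays, scaling factors and initial conditions.

    Every field is a non-negative finite float; ``R_tot`` and the three
    immunoblot scaling factors must be strictly positive.  Instances are
    immutable; use :meth:`replace` to derive perturbed sets.
    """

    k_act: float  # receptor activation, 1/(min·(ng/ml))
    k_inact: float  # active-receptor deactivation, 1/min
    R_tot: float  # total receptor pool, a.u.
    k_phos: float  # STAT1 phosphorylation per active receptor, 1/(min·a.u.)
    k_inh: float  # SOCS1 feedback inhibition constant, 1/a.u.
    k_impD: float  # nuclear import of phospho-STAT1, 1/min
    k_impU: float  # nuclear import of unphosphorylated STAT1, 1/min
    k_exp: float  # nuclear export of unphosphorylated STAT1, 1/min
    k_deph: float  # nuclear dephosphorylation, 1/min
    k_tc_socs: float  # SOCS1 transcription per nuclear phospho-STAT1, 1/min
    d_m_socs: float  # SOCS1 mRNA degradation, 1/min
    k_tl_socs: float  # SOCS1 translation, 1/min
    d_socs: float  # SOCS1 protein degradation, 1/min
    b_m_stat: float  # basal STAT1 mRNA synthesis, a.u./min
    k_tc_stat: float  # induced STAT1 transcription, 1/min
    d_m_stat: float  # STAT1 mRNA degradation, 1/min
    k_tl_stat: float  # STAT1 translation, 1/min
    d_stat: float  # STAT1 protein turnover, 1/min
    tau_socs: float  # transcriptional delay for SOCS1, min
    tau_stat: float  # transcriptional delay for STAT1, min
    s_pstat: float = 1.0  # immunoblot scaling factor for phospho-STAT1
    s_stat: float = 1.0  # immunoblot scaling factor for total STAT1
    s_socs: float = 1.0  # scaling factor for SOCS1 mRNA
    v_nc: float = 1.0  # cytoplasm:nucleus volume ratio entering IF ratios
    stat1_uc0: float = 1.0  # initial cytoplasmic unphosphorylated STAT1, a.u.
    stat1_un0: float = 0.0  # initial nuclear unphosphorylated STAT1, a.u.

    def __post_init__(self) -> None:
        import math

        for name, value in self.items():
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise TypeError(f"parameter {name!r} must be a number, got {value!r}")
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value!r}")
        if self.R_tot <= 0:
            raise ValueError("R_tot must be > 0")
        for name in ("s_pstat", "s_stat", "s_socs", "v_nc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"scaling factor {name} must be > 0")

    # -- mapping-like access -------------------------------------------------

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def items(self) -> Iterator[tuple[str, float]]:
        for name in self.field_names():
            yield name, getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {name: float(value) for name, value in self.items()}

    def __getitem__(self, name: str) -> float:
        if name not in self.field_names():
            raise KeyError(name)
        return getattr(self, name)

    def replace(self, **changes: float) -> "PathwayParameters":
        return dataclasses.replace(self, **changes)

    # -- serialization -------------------------------------------------------

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "PathwayParameters":
        known = set(cls.field_names())
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        missing = {
            f.name
            for f in dataclasses.fields(cls)
            if f.default is dataclasses.MISSING
        } - set(mapping)
        if missing:
            raise KeyError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.as_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(payload, sort_keys=True))
        else:
            path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PathwayParameters":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        if not isinstance(payload, Mapping):
            raise ValueError(f"{path}: expected a flat mapping of name -> value")
        return cls.from_dict(payload)


def consistent_initial_stat1(
    params: PathwayParameters, total: float = 1.0
) -> tuple[float, float]:
    """Split a total unphosphorylated STAT1 pool into (cytoplasmic, nuclear)
    amounts that are at steady state with respect to shuttling and turnover.

    With synthesis ``k_tl_stat·b_m_stat/d_m_stat`` the absolute pool size is
    fixed by the turnover balance and ``total`` is ignored; without turnover
    only the nuclear:cytoplasmic split is constrained and ``total`` sets the
    pool size.
    """
    synth = params.k_tl_stat * (
        params.b_m_stat / params.d_m_stat if params.d_m_stat > 0 else 0.0
    )
    if params.d_stat > 0 and synth > 0:
        denom = (
            params.k_impU
            + params.d_stat
            - params.k_exp * params.k_impU / (params.k_exp + params.d_stat)
        )
        uc = synth / denom
        un = params.k_impU * uc / (params.k_exp + params.d_stat)
        return uc, un
    if synth > 0 and params.d_stat == 0:
        raise ValueError("no finite basal state: synthesis without turnover")
    if params.d_stat > 0:  # turnover without synthesis: pool drains to zero
        return 0.0, 0.0
    # conservative pool: only the shuttling split is constrained
    k_out = params.k_exp + params.d_stat
    if params.k_impU == 0 and k_out == 0:
        return total, 0.0
    uc = total * k_out / (params.k_impU + k_out) if (params.k_impU + k_out) else total
    un = total - uc
    return uc, un
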