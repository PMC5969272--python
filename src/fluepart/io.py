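"""Reading and writing site tables in a FLUXNET-style CSV dialect.

Daily site tables use the standard daily variable names (TA_F, SW_IN_F,
VPD_F, P_F, NETRAD, LE_F_MDS, GPP_NT_VUT_REF, GPP_DT_VUT_REF plus *_QC
gap-fill fractions); greenness extracts are (date, evi, qa) tables and
ground-truth parameters round-trip through a YAML sidecar.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .types import SyntheticConfig, TruthParams

_TO_FLUXNET = {
    "ta": "TA_F",
    "sw_in": "SW_IN_F",
    "vpd": "VPD_F",
    "precip": "P_F",
    "netrad": "NETRAD",
    "le": "LE_F_MDS",
    "gpp_nt": "GPP_NT_VUT_REF",
    "gpp_dt": "GPP_DT_VUT_REF",
    "gpp_qc_frac": "NEE_VUT_REF_QC",
    "le_qc_frac": "LE_F_MDS_QC",
    "par": "PAR",
    "evi_true_daily": "EVI_TRUE",
}
_FROM_FLUXNET = {v: k for k, v in _TO_FLUXNET.items()}


def write_site_table(series: pd.DataFrame, path) -> None:
    out = series.rename(columns=_TO_FLUXNET).copy()
    out.insert(0, "TIMESTAMP", out.index.strftime("%Y%m%d"))
    out.to_csv(path, index=False, float_format="%.6f")


def read_site_table(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    raw["date"] = pd.to_datetime(raw.pop("TIMESTAMP"), format="%Y%m%d")
    raw = raw.set_index("date")
    return raw.rename(columns=_FROM_FLUXNET)


def write_evi_table(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False, float_format="%.6f")


def read_evi_table(path) -> pd.DataFrame:
    raw = pd.read_csv(path, parse_dates=["date"])
    return raw.set_index("date")


def write_truth_sidecar(truth: TruthParams, config: SyntheticConfig, path
                        ) -> None:
    payload = {
        "truth": dataclasses.asdict(truth),
        "config": dataclasses.asdict(config),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_truth_sidecar(path) -> tuple[TruthParams, SyntheticConfig]:
    payload = yaml.safe_load(Path(path).read_text())
    cfg = payload["config"]
    cfg["dry_spell_blocks"] = tuple(tuple(b) for b in cfg["dry_spell_blocks"])
    cfg["vpd_coupling"] = tuple(cfg["vpd_coupling"])
    return TruthParams(**payload["truth"]), SyntheticConfig(**cfg)


def write_flue_table(flue_ensemble: pd.DataFrame, path) -> None:
    out = flue_ensemble.copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False, float_format="%.6f")


def write_soil_moisture_table(sm: pd.DataFrame, path) -> None:
    out = sm.copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.insert(1, "source", sm.attrs.get("source", ""))
    out.to_csv(path, index=False, float_format="%.6f")
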