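"""EHR table ingestion, validation and drug-catalog normalization.

The unit of analysis is one hospitalization record.  Four delimited tables
(comma-separated, UTF-8, header row) describe a dataset:

- ``admissions.csv``: record_id, patient_id, age, sex, admission_time,
  discharge_time, main_diagnosis, all_diagnoses (';'-separated)
- ``scr_results.csv``: record_id, report_time, scr (umol/L)
- ``drug_admins.csv``: record_id, drug_id, atc_code, first_time, last_time
- ``drug_catalog.csv``: drug_id, ingredient, atc_code, pharm_class

Timestamps are ISO-8601 at minute resolution; interval comparisons against a
stay are half-open [admission, discharge).  Rows violating an invariant are
rejected, not repaired, and land in a reject report (table, row, record_id,
rule).  Diagnosis codes are opaque strings matched exactly or by prefix.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .renal_function import AGE_MAX_YEARS, AGE_MIN_YEARS

__all__ = [
    "ADMISSION_COLUMNS",
    "SCR_COLUMNS",
    "DRUG_ADMIN_COLUMNS",
    "CATALOG_COLUMNS",
    "SchemaError",
    "CodeLists",
    "EHRBundle",
    "CatalogNormalization",
    "read_tables",
    "validate_bundle",
    "write_tables",
    "normalize_drug_catalog",
    "records_with_codes",
]

ADMISSION_COLUMNS = [
    "record_id", "patient_id", "age", "sex",
    "admission_time", "discharge_time", "main_diagnosis", "all_diagnoses",
]
SCR_COLUMNS = ["record_id", "report_time", "scr"]
DRUG_ADMIN_COLUMNS = ["record_id", "drug_id", "atc_code", "first_time", "last_time"]
CATALOG_COLUMNS = ["drug_id", "ingredient", "atc_code", "pharm_class"]

TIME_FORMAT = "%Y-%m-%dT%H:%M"


class SchemaError(ValueError):
    """A required column is missing or a file is structurally unusable."""


@dataclass(frozen=True)
class CodeLists:
    """Configuration code lists driving exclusions and calibration.

    kidney_disease_codes are diagnosis codes (matched per `match_mode`);
    the three drug sets hold catalog drug_ids and must be mutually disjoint.
    """

    kidney_disease_codes: frozenset[str] = frozenset()
    kidney_protecting_drugs: frozenset[str] = frozenset()
    solvent_drugs: frozenset[str] = frozenset()
    external_drugs: frozenset[str] = frozenset()
    match_mode: str = "prefix"  # 'prefix' or 'exact' for diagnosis codes

    def __post_init__(self) -> None:
        pairs = [
            ("kidney_protecting_drugs", "solvent_drugs"),
            ("kidney_protecting_drugs", "external_drugs"),
            ("solvent_drugs", "external_drugs"),
        ]
        for a, b in pairs:
            overlap = getattr(self, a) & getattr(self, b)
            if overlap:
                raise ValueError(f"code lists {a} and {b} overlap: {sorted(overlap)}")
        if self.match_mode not in ("prefix", "exact"):
            raise ValueError("match_mode must be 'prefix' or 'exact'")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CodeLists":
        return cls(
            kidney_disease_codes=frozenset(d.get("kidney_disease_codes", [])),
            kidney_protecting_drugs=frozenset(d.get("kidney_protecting_drugs", [])),
            solvent_drugs=frozenset(d.get("solvent_drugs", [])),
            external_drugs=frozenset(d.get("external_drugs", [])),
            match_mode=d.get("match_mode", "prefix"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeLists":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "kidney_disease_codes": sorted(self.kidney_disease_codes),
            "kidney_protecting_drugs": sorted(self.kidney_protecting_drugs),
            "solvent_drugs": sorted(self.solvent_drugs),
            "external_drugs": sorted(self.external_drugs),
            "match_mode": self.match_mode,
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def remapped(self, remap: Mapping[str, str]) -> "CodeLists":
        """Translate drug ids through a catalog-normalization remap."""
        f = lambda ids: frozenset(remap.get(i, i) for i in ids)
        return dataclasses.replace(
            self,
            kidney_protecting_drugs=f(self.kidney_protecting_drugs),
            solvent_drugs=f(self.solvent_drugs),
            external_drugs=f(self.external_drugs),
        )


@dataclass
class EHRBundle:
    """Validated dataset: four tables plus the code lists."""

    admissions: pd.DataFrame
    scr_results: pd.DataFrame
    drug_admins: pd.DataFrame
    drug_catalog: pd.DataFrame
    code_lists: CodeLists = field(default_factory=CodeLists)

    @property
    def n_records(self) -> int:
        return len(self.admissions)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _parse_times(df: pd.DataFrame, col: str) -> pd.Series:
    return pd.to_datetime(df[col], errors="coerce", format="ISO8601")


def _reject(rows: list, table: str, idx: pd.Index, rule: str, record_ids: pd.Series) -> None:
    for i in idx:
        rows.append({"table": table, "row": int(i) + 2, "record_id": record_ids.loc[i], "rule": rule})


def validate_bundle(
    admissions: pd.DataFrame,
    scr_results: pd.DataFrame,
    drug_admins: pd.DataFrame,
    drug_catalog: pd.DataFrame,
    code_lists: CodeLists | None = None,
) -> tuple[EHRBundle, pd.DataFrame]:
    """Enforce all type invariants; return (bundle of clean rows, reject report).

    The reject report lists one row per violated rule with the 1-based file
    row number (header = row 1).  Rows in dependent tables that reference a
    rejected or unknown admission are themselves rejected.
    """
    rejects: list[dict] = []

    adm = admissions.copy().reset_index(drop=True)
    _require_columns(adm, ADMISSION_COLUMNS, "admissions")
    adm["age"] = pd.to_numeric(adm["age"], errors="coerce")
    adm["sex"] = adm["sex"].astype(str).str.strip().str.lower()
    adm["admission_time"] = _parse_times(adm, "admission_time")
    adm["discharge_time"] = _parse_times(adm, "discharge_time")
    rid = adm["record_id"].astype(str)

    bad = adm.index[adm["age"].isna()]
    _reject(rejects, "admissions", bad, "unparsable_age", rid)
    ok = adm["age"].notna()
    bad = adm.index[ok & ((adm["age"] < AGE_MIN_YEARS) | (adm["age"] >= AGE_MAX_YEARS))]
    _reject(rejects, "admissions", bad, "age_ineligible", rid)
    bad = adm.index[~adm["sex"].isin(["male", "female"])]
    _reject(rejects, "admissions", bad, "invalid_sex", rid)
    bad = adm.index[adm["admission_time"].isna() | adm["discharge_time"].isna()]
    _reject(rejects, "admissions", bad, "unparsable_timestamp", rid)
    tok = adm["admission_time"].notna() & adm["discharge_time"].notna()
    bad = adm.index[tok & (adm["admission_time"] >= adm["discharge_time"])]
    _reject(rejects, "admissions", bad, "discharge_not_after_admission", rid)
    main_in_all = [
        str(m) in str(a).split(";")
        for m, a in zip(adm["main_diagnosis"], adm["all_diagnoses"])
    ]
    bad = adm.index[~np.asarray(main_in_all)]
    _reject(rejects, "admissions", bad, "main_diagnosis_not_in_all", rid)
    bad = adm.index[adm["record_id"].duplicated(keep=False)]
    _reject(rejects, "admissions", bad, "duplicate_record_id", rid)

    rejected_adm = {r["row"] - 2 for r in rejects if r["table"] == "admissions"}
    adm_clean = adm.drop(index=sorted(rejected_adm)).reset_index(drop=True)
    known = set(adm_clean["record_id"].astype(str))
    stays = adm_clean.set_index("record_id")[["admission_time", "discharge_time"]]

    scr = scr_results.copy().reset_index(drop=True)
    _require_columns(scr, SCR_COLUMNS, "scr_results")
    scr["report_time"] = _parse_times(scr, "report_time")
    scr["scr"] = pd.to_numeric(scr["scr"], errors="coerce")
    srid = scr["record_id"].astype(str)
    bad = scr.index[~srid.isin(known)]
    _reject(rejects, "scr_results", bad, "unknown_record", srid)
    bad = scr.index[scr["report_time"].isna()]
    _reject(rejects, "scr_results", bad, "unparsable_timestamp", srid)
    bad = scr.index[scr["scr"].isna() | (scr["scr"] <= 0) | ~np.isfinite(scr["scr"].fillna(np.inf))]
    _reject(rejects, "scr_results", bad, "scr_not_positive", srid)
    joined = scr.join(stays, on="record_id")
    in_stay = (
        joined["report_time"].notna()
        & joined["admission_time"].notna()
        & (joined["report_time"] >= joined["admission_time"])
        & (joined["report_time"] < joined["discharge_time"])
    )
    bad = scr.index[srid.isin(known) & scr["report_time"].notna() & ~in_stay]
    _reject(rejects, "scr_results", bad, "report_time_outside_stay", srid)
    rejected = {r["row"] - 2 for r in rejects if r["table"] == "scr_results"}
    scr_clean = scr.drop(index=sorted(rejected)).reset_index(drop=True)

    dr = drug_admins.copy().reset_index(drop=True)
    _require_columns(dr, DRUG_ADMIN_COLUMNS, "drug_admins")
    dr["first_time"] = _parse_times(dr, "first_time")
    dr["last_time"] = _parse_times(dr, "last_time")
    drid = dr["record_id"].astype(str)
    bad = dr.index[~drid.isin(known)]
    _reject(rejects, "drug_admins", bad, "unknown_record", drid)
    bad = dr.index[dr["first_time"].isna() | dr["last_time"].isna()]
    _reject(rejects, "drug_admins", bad, "unparsable_timestamp", drid)
    tok = dr["first_time"].notna() & dr["last_time"].notna()
    bad = dr.index[tok & (dr["first_time"] > dr["last_time"])]
    _reject(rejects, "drug_admins", bad, "first_after_last", drid)
    joined = dr.join(stays, on="record_id")
    in_stay = (
        joined["admission_time"].notna()
        & (joined["first_time"] >= joined["admission_time"])
        & (joined["last_time"] < joined["discharge_time"])
    )
    bad = dr.index[drid.isin(known) & tok & ~in_stay]
    _reject(rejects, "drug_admins", bad, "administration_outside_stay", drid)
    rejected = {r["row"] - 2 for r in rejects if r["table"] == "drug_admins"}
    dr_clean = dr.drop(index=sorted(rejected)).reset_index(drop=True)

    cat = drug_catalog.copy().reset_index(drop=True)
    _require_columns(cat, CATALOG_COLUMNS, "drug_catalog")
    bad = cat.index[cat["drug_id"].duplicated(keep=False)]
    _reject(rejects, "drug_catalog", bad, "duplicate_drug_id", cat["drug_id"].astype(str))
    rejected = {r["row"] - 2 for r in rejects if r["table"] == "drug_catalog"}
    cat_clean = cat.drop(index=sorted(rejected)).reset_index(drop=True)

    reject_df = pd.DataFrame(rejects, columns=["table", "row", "record_id", "rule"])
    bundle = EHRBundle(adm_clean, scr_clean, dr_clean, cat_clean, code_lists or CodeLists())
    return bundle, reject_df


def read_tables(
    data_dir: str | Path,
    codelists_path: str | Path | None = None,
    *,
    admissions: str = "admissions.csv",
    scr_results: str = "scr_results.csv",
    drug_admins: str = "drug_admins.csv",
    drug_catalog: str = "drug_catalog.csv",
) -> tuple[EHRBundle, pd.DataFrame]:
    """Read and validate the four CSVs (+ optional YAML code lists)."""
    data_dir = Path(data_dir)
    frames = {}
    for name, fname in (
        ("admissions", admissions),
        ("scr_results", scr_results),
        ("drug_admins", drug_admins),
        ("drug_catalog", drug_catalog),
    ):
        path = data_dir / fname
        if not path.exists():
            raise FileNotFoundError(f"required input {path} does not exist")
        frames[name] = pd.read_csv(path, dtype=str, keep_default_na=False)
    code_lists = CodeLists.from_yaml(codelists_path) if codelists_path else CodeLists()
    return validate_bundle(
        frames["admissions"], frames["scr_results"], frames["drug_admins"],
        frames["drug_catalog"], code_lists,
    )


def _fmt_times(df: pd.DataFrame, cols: Iterable[str]) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        if c in out.columns and pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = out[c].dt.strftime(TIME_FORMAT)
    return out


def write_tables(bundle: EHRBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle back to CSV; a write/read cycle is lossless."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    adm = _fmt_times(bundle.admissions[ADMISSION_COLUMNS], ["admission_time", "discharge_time"])
    scr = _fmt_times(bundle.scr_results[SCR_COLUMNS], ["report_time"])
    dr = _fmt_times(bundle.drug_admins[DRUG_ADMIN_COLUMNS], ["first_time", "last_time"])
    cat = bundle.drug_catalog[CATALOG_COLUMNS]
    for name, df in (
        ("admissions", adm), ("scr_results", scr),
        ("drug_admins", dr), ("drug_catalog", cat),
    ):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    bundle.code_lists.to_yaml(out_dir / "code_lists.yaml")
    paths["code_lists"] = out_dir / "code_lists.yaml"
    return paths


@dataclass
class CatalogNormalization:
    """Canonical catalog plus a total remap from input drug_id to canonical drug_id."""

    catalog: pd.DataFrame
    remap: dict[str, str]
    warnings: list[str]


def normalize_drug_catalog(catalog: pd.DataFrame) -> CatalogNormalization:
    """Collapse catalog entries sharing (normalized ingredient, ATC) to one drug.

    Ingredient normalization: case-fold, trim, collapse internal whitespace.
    Entries with the same ingredient but different ATC codes stay distinct
    (a warning is emitted).  The canonical id of a group is its smallest
    drug_id, making the operation idempotent.
    """
    if len(catalog) == 0:
        raise ValueError("drug catalog is empty")
    cat = catalog.copy()
    cat["_ingredient_norm"] = (
        cat["ingredient"].astype(str).str.strip().str.lower().str.split().str.join(" ")
    )
    cat["_atc_norm"] = cat["atc_code"].astype(str).str.strip().str.upper().replace({"NAN": ""})
    warnings: list[str] = []
    multi_atc = cat.groupby("_ingredient_norm")["_atc_norm"].nunique()
    for ing in multi_atc.index[multi_atc > 1]:
        codes = sorted(cat.loc[cat["_ingredient_norm"] == ing, "_atc_norm"].unique())
        warnings.append(
            f"ingredient {ing!r} carries conflicting ATC codes {codes}; kept distinct"
        )
    remap: dict[str, str] = {}
    rows = []
    for (_ing, _atc), grp in cat.groupby(["_ingredient_norm", "_atc_norm"], sort=True):
        canonical = grp["drug_id"].astype(str).min()
        for d in grp["drug_id"].astype(str):
            remap[d] = canonical
        first = grp.sort_values("drug_id").iloc[0]
        rows.append({
            "drug_id": canonical,
            "ingredient": first["ingredient"],
            "atc_code": first["atc_code"],
            "pharm_class": first["pharm_class"],
            "n_merged": len(grp),
        })
    canon = pd.DataFrame(rows).sort_values("drug_id").reset_index(drop=True)
    return CatalogNormalization(catalog=canon, remap=remap, warnings=warnings)


def records_with_codes(
    admissions: pd.DataFrame, codes: Iterable[str], match_mode: str = "prefix"
) -> pd.Series:
    """Boolean Series (indexed by record_id): record carries any listed diagnosis code."""
    codes = list(codes)
    exploded = admissions[["record_id", "all_diagnoses"]].copy()
    exploded["all_diagnoses"] = exploded["all_diagnoses"].astype(str).str.split(";")
    exploded = exploded.explode("all_diagnoses")
    dx = exploded["all_diagnoses"].astype(str).str.strip()
    if not codes:
        hit = pd.Series(False, index=exploded.index)
    elif match_mode == "exact":
        hit = dx.isin(set(codes))
    else:
        hit = dx.str.startswith(tuple(codes))
    flagged = exploded.loc[hit, "record_id"].unique()
    out = pd.Series(False, index=pd.Index(admissions["record_id"], name="record_id"))
    out.loc[out.index.isin(flagged)] = True
    return out
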