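"""Readers and writers for the package's tabular and config formats.

All tabular I/O is UTF-8 CSV with a header row, no index column, and a
versioned schema comment on the first line (``# tetherdrive-<kind>-csv v1``).
Readers validate eagerly and raise :class:`FileFormatError` with the
offending file line number and field, so malformed data fails loudly at the
boundary instead of deep inside a likelihood evaluation.

Formats
-------
* cross CSV: vial_id, mother_genotype, father_genotype, n_egfp, n_dsred,
  n_both, n_neither, n_eggs, n_pupae
* cage CSV: generation, census, n_egfp_only, n_dsred_only, n_both, n_neither
  (phenotype counts must sum to the census per row)
* params YAML: drive_params / fitness / cage sections
* fit JSON: serialized :class:`~tetherdrive.likelihood.LikelihoodFit`
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .cage import CageConfig, CageTrajectory
from .dynamics import FitnessComponent, FitnessModel, ReleaseEvent
from .genetics import DriveParams, HomingLocusRule, parse_diplotype, parse_genotype
from .likelihood import LikelihoodFit

__all__ = [
    "FileFormatError",
    "SCHEMA_VERSION",
    "write_cross_csv",
    "read_cross_csv",
    "write_cage_csv",
    "read_cage_csv",
    "write_config",
    "read_config",
    "write_fit_json",
    "read_fit_json",
]

SCHEMA_VERSION = 1

_CROSS_HEADER = f"# tetherdrive-cross-csv v{SCHEMA_VERSION}"
_CAGE_HEADER = f"# tetherdrive-cage-csv v{SCHEMA_VERSION}"

_CROSS_COLUMNS = [
    "vial_id",
    "mother_genotype",
    "father_genotype",
    "n_egfp",
    "n_dsred",
    "n_both",
    "n_neither",
    "n_eggs",
    "n_pupae",
]
_CROSS_COUNTS = ["n_egfp", "n_dsred", "n_both", "n_neither", "n_eggs", "n_pupae"]

_CAGE_COLUMNS = [
    "generation",
    "census",
    "n_egfp_only",
    "n_dsred_only",
    "n_both",
    "n_neither",
]
_CAGE_COUNTS = ["n_egfp_only", "n_dsred_only", "n_both", "n_neither"]


class FileFormatError(ValueError):
    """A file failed schema or content validation; the message says where."""


# ---------------------------------------------------------------------------
# shared helpers


def _write_with_header(df: pd.DataFrame, path: Union[str, Path], header: str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def _read_with_header(
    path: Union[str, Path], expected_header: str
) -> pd.DataFrame:
    path = Path(path)
    try:
        with path.open("r", encoding="utf-8") as fh:
            first = fh.readline().rstrip("\n")
            if first.strip() != expected_header:
                raise FileFormatError(
                    f"{path}, line 1: expected schema header {expected_header!r}, "
                    f"found {first!r}"
                )
            df = pd.read_csv(fh)
    except pd.errors.EmptyDataError as exc:
        raise FileFormatError(f"{path}: no data after the schema header") from exc
    return df


def _require_columns(
    df: pd.DataFrame, columns: List[str], path: Union[str, Path]
) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FileFormatError(
            f"{path}, line 2: missing column(s) {missing}; expected {columns}"
        )
    extra = [c for c in df.columns if c not in columns]
    if extra:
        raise FileFormatError(
            f"{path}, line 2: unexpected column(s) {extra}; expected {columns}"
        )


def _check_count_column(
    df: pd.DataFrame, col: str, path: Union[str, Path]
) -> None:
    # data rows start on file line 3: schema comment + header row come first
    series = df[col]
    if series.isna().any():
        row = int(series.isna().idxmax())
        raise FileFormatError(f"{path}, line {row + 3}: missing value in {col!r}")
    as_float = pd.to_numeric(series, errors="coerce")
    if as_float.isna().any() or not np.allclose(as_float, np.round(as_float)):
        bad = int((as_float.isna() | (as_float != np.round(as_float))).idxmax())
        raise FileFormatError(
            f"{path}, line {bad + 3}: {col!r} must be a non-negative integer, "
            f"found {series.iloc[bad]!r}"
        )
    if (as_float < 0).any():
        row = int((as_float < 0).idxmax())
        raise FileFormatError(
            f"{path}, line {row + 3}: negative count {series.iloc[row]!r} in {col!r}"
        )


# ---------------------------------------------------------------------------
# cross CSV


def write_cross_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    _require_columns(df[_CROSS_COLUMNS] if set(_CROSS_COLUMNS) <= set(df.columns) else df,
                     _CROSS_COLUMNS, path)
    _write_with_header(df[_CROSS_COLUMNS], path, _CROSS_HEADER)


def read_cross_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = _read_with_header(path, _CROSS_HEADER)
    _require_columns(df, _CROSS_COLUMNS, path)
    for col in _CROSS_COUNTS:
        _check_count_column(df, col, path)
    df = df.astype({c: int for c in _CROSS_COUNTS})
    pupae = df[["n_egfp", "n_dsred", "n_both", "n_neither"]].sum(axis=1)
    over = pupae > df["n_pupae"]
    if over.any():
        row = int(over.idxmax())
        raise FileFormatError(
            f"{path}, line {row + 3}: phenotype counts sum to {pupae.iloc[row]} "
            f"but n_pupae is {df['n_pupae'].iloc[row]}"
        )
    egg_under = df["n_pupae"] > df["n_eggs"]
    if egg_under.any():
        row = int(egg_under.idxmax())
        raise FileFormatError(
            f"{path}, line {row + 3}: n_pupae {df['n_pupae'].iloc[row]} exceeds "
            f"n_eggs {df['n_eggs'].iloc[row]}"
        )
    for col in ("mother_genotype", "father_genotype"):
        for i, text in enumerate(df[col]):
            try:
                parse_genotype(str(text))
            except ValueError as exc:
                raise FileFormatError(
                    f"{path}, line {i + 3}: unparseable {col} {text!r}: {exc}"
                ) from exc
    return df


# ---------------------------------------------------------------------------
# cage CSV


def write_cage_csv(
    traj: Union[CageTrajectory, pd.DataFrame], path: Union[str, Path]
) -> None:
    df = traj.counts if isinstance(traj, CageTrajectory) else traj
    _require_columns(df, _CAGE_COLUMNS, path)
    _write_with_header(df[_CAGE_COLUMNS], path, _CAGE_HEADER)


def read_cage_csv(path: Union[str, Path]) -> CageTrajectory:
    df = _read_with_header(path, _CAGE_HEADER)
    _require_columns(df, _CAGE_COLUMNS, path)
    for col in _CAGE_COUNTS + ["census", "generation"]:
        _check_count_column(df, col, path)
    df = df.astype({c: int for c in _CAGE_COLUMNS})
    sums = df[_CAGE_COUNTS].sum(axis=1)
    bad = sums != df["census"]
    if bad.any():
        row = int(bad.idxmax())
        raise FileFormatError(
            f"{path}, line {row + 3}: phenotype counts sum to {sums.iloc[row]} "
            f"but census is {df['census'].iloc[row]}"
        )
    gens = df["generation"].to_numpy()
    if not np.array_equal(gens, np.arange(len(gens))):
        raise FileFormatError(
            f"{path}: generations must be consecutive from 0, found {list(gens)}"
        )
    return CageTrajectory(counts=df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# params / config YAML


def _prob(cfg: Dict, section: str, key: str, default: float) -> float:
    v = float(cfg.get(key, default))
    if not (0.0 <= v <= 1.0):
        raise FileFormatError(
            f"config field {section}.{key} = {v} is not a probability in [0, 1]"
        )
    return v


def read_config(path: Union[str, Path]) -> Dict:
    """Load a YAML config into {'params', 'fitness', 'cage'} model objects.

    Sections are optional; missing ones yield defaults (``cage`` yields None
    since it has no meaningful default length).  Field errors name the field.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FileFormatError(f"{path}: top level must be a mapping")
    known = {"drive_params", "fitness", "cage"}
    unknown = set(raw) - known
    if unknown:
        raise FileFormatError(f"{path}: unknown section(s) {sorted(unknown)}")

    dp = raw.get("drive_params", {}) or {}
    rule = dp.get("homing_locus_rule", "none")
    try:
        rule = HomingLocusRule(rule)
    except ValueError as exc:
        raise FileFormatError(
            f"config field drive_params.homing_locus_rule = {rule!r}; valid: "
            f"{[r.value for r in HomingLocusRule]}"
        ) from exc
    try:
        params = DriveParams(
            c_germ_tare=_prob(dp, "drive_params", "c_germ_tare", 0.0),
            c_embryo_tare=_prob(dp, "drive_params", "c_embryo_tare", 0.0),
            homing_germ_cut=_prob(dp, "drive_params", "homing_germ_cut", 0.0),
            homing_conversion_frac=_prob(dp, "drive_params", "homing_conversion_frac", 0.0),
            c_embryo_homing=_prob(dp, "drive_params", "c_embryo_homing", 0.0),
            recomb_female=_prob(dp, "drive_params", "recomb_female", 0.5),
            recomb_male=_prob(dp, "drive_params", "recomb_male", 0.0),
            homing_locus_rule=rule,
        )
    except ValueError as exc:
        raise FileFormatError(f"{path}: drive_params: {exc}") from exc

    ft = raw.get("fitness", {}) or {}
    comp = ft.get("component", "both_sexes")
    try:
        comp = FitnessComponent(comp)
    except ValueError as exc:
        raise FileFormatError(
            f"config field fitness.component = {comp!r}; valid: "
            f"{[c.value for c in FitnessComponent]}"
        ) from exc
    for key in ("f_hom", "f_hom_homing"):
        if key in ft and not (0.0 < float(ft[key])):
            raise FileFormatError(f"config field fitness.{key} must be positive")
    fitness = FitnessModel(
        f_hom=float(ft.get("f_hom", 1.0)),
        f_hom_homing=float(ft.get("f_hom_homing", 1.0)),
        component=comp,
    )

    cage: Optional[CageConfig] = None
    if "cage" in raw and raw["cage"]:
        cg = raw["cage"]
        releases = []
        for i, rel in enumerate(cg.get("releases", [])):
            try:
                releases.append(
                    ReleaseEvent(
                        generation=int(rel["generation"]),
                        genotype=parse_diplotype(rel["genotype"]),
                        proportion=float(rel["proportion"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FileFormatError(
                    f"config field cage.releases[{i}]: {exc}"
                ) from exc
        try:
            cage = CageConfig(
                n_generations=int(cg["n_generations"]),
                census_sizes=cg.get("census_sizes", 3500),
                ne_fraction=_prob(cg, "cage", "ne_fraction", 0.036),
                releases=tuple(releases),
                seed=int(cg.get("seed", 0)),
            )
        except (KeyError, ValueError) as exc:
            raise FileFormatError(f"{path}: cage: {exc}") from exc

    return {"params": params, "fitness": fitness, "cage": cage}


def write_config(
    path: Union[str, Path],
    params: DriveParams,
    fitness: Optional[FitnessModel] = None,
    cage: Optional[CageConfig] = None,
) -> None:
    from .genetics import format_diplotype

    doc: Dict = {
        "drive_params": {
            "c_germ_tare": params.c_germ_tare,
            "c_embryo_tare": params.c_embryo_tare,
            "homing_germ_cut": params.homing_germ_cut,
            "homing_conversion_frac": params.homing_conversion_frac,
            "c_embryo_homing": params.c_embryo_homing,
            "recomb_female": params.recomb_female,
            "recomb_male": params.recomb_male,
            "homing_locus_rule": params.homing_locus_rule.value,
        }
    }
    if fitness is not None:
        doc["fitness"] = {
            "f_hom": fitness.f_hom,
            "f_hom_homing": fitness.f_hom_homing,
            "component": fitness.component.value,
        }
    if cage is not None:
        doc["cage"] = {
            "n_generations": cage.n_generations,
            "census_sizes": cage.census_sizes
            if isinstance(cage.census_sizes, int)
            else list(cage.census_sizes),
            "ne_fraction": cage.ne_fraction,
            "seed": cage.seed,
            "releases": [
                {
                    "generation": r.generation,
                    "genotype": format_diplotype(r.genotype),
                    "proportion": r.proportion,
                }
                for r in cage.releases
            ],
        }
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# fit JSON


def write_fit_json(fit: LikelihoodFit, path: Union[str, Path]) -> None:
    doc = {
        "schema": f"tetherdrive-fit-json v{SCHEMA_VERSION}",
        "f_hom": fit.f_hom,
        "component": fit.component.value,
        "ne_fraction": fit.ne_fraction,
        "loglik": fit.loglik,
        "ci_f_hom": list(fit.ci_f_hom),
        "ci_ne_fraction": list(fit.ci_ne_fraction),
        "per_transition": fit.per_transition.to_dict(orient="records"),
        "transitions_discarded": fit.transitions_discarded,
        "converged": fit.converged,
        "message": fit.message,
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_fit_json(path: Union[str, Path]) -> LikelihoodFit:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        doc = json.load(fh)
    expected = f"tetherdrive-fit-json v{SCHEMA_VERSION}"
    if doc.get("schema") != expected:
        raise FileFormatError(
            f"{path}: schema {doc.get('schema')!r}, expected {expected!r}"
        )
    try:
        return LikelihoodFit(
            f_hom=float(doc["f_hom"]),
            component=FitnessComponent(doc["component"]),
            ne_fraction=float(doc["ne_fraction"]),
            loglik=float(doc["loglik"]),
            ci_f_hom=tuple(doc["ci_f_hom"]),
            ci_ne_fraction=tuple(doc["ci_ne_fraction"]),
            per_transition=pd.DataFrame(
                doc["per_transition"], columns=["cage", "transition", "loglik"]
            ),
            transitions_discarded=int(doc["transitions_discarded"]),
            converged=bool(doc["converged"]),
            message=str(doc.get("message", "")),
        )
    except (KeyError, ValueError) as exc:
        raise FileFormatError(f"{path}: malformed fit JSON: {exc}") from exc
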