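"""Table readers/writers with schema validation, and seeded fixtures.

The interchange format is delimited text (TSV by default, comma
accepted) with a header; column names, not order, are the contract.
Three schemas are defined: ``cells`` (basal-layer cell records),
``events`` (scored division doublets) and ``counts`` (shRNA screen
counts).  Enumerated columns are accepted case-insensitively and
normalised to lowercase on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from . import simulator as sim

logger = logging.getLogger(__name__)

__all__ = ["SCHEMAS", "read_table", "write_table", "validate_table", "make_fixtures"]

_BOOL01 = {"0", "1", "true", "false"}

SCHEMAS: dict[str, dict] = {
    "cells": {
        "required": [
            "animal_id", "clone_id", "cell_id", "x_um", "y_um",
            "layer", "genotype", "edu", "brdu", "k10",
        ],
        "enums": {
            "layer": {"basal", "suprabasal"},
            "genotype": {"wt", "hrasg12v", "other"},
        },
        "floats": ["x_um", "y_um"],
        "bools": ["edu", "brdu", "k10"],
    },
    "events": {
        "required": [
            "animal_id", "clone_id", "context", "week",
            "daughter1_layer", "daughter2_layer",
            "daughter1_morph", "daughter2_morph",
        ],
        "enums": {
            "context": {
                "single_cell", "clone_edge", "clone_inner",
                "wt_adjacent", "wt_distant", "field",
            },
            "daughter1_layer": {"basal", "suprabasal"},
            "daughter2_layer": {"basal", "suprabasal"},
            "daughter1_morph": {"cuboidal", "squamous", "unknown"},
            "daughter2_morph": {"cuboidal", "squamous", "unknown"},
        },
        "floats": ["week"],
        "bools": [],
    },
    "counts": {
        "required": ["gene", "shrna_id", "compartment", "replicate", "count"],
        "enums": {"compartment": {"basal", "suprabasal"}},
        "floats": [],
        "bools": [],
        "ints": ["count"],
    },
}

_GENOTYPE_CANON = {"wt": "WT", "hrasg12v": "HrasG12V", "other": "other"}


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Validate and normalise a table against a named schema.

    Enumerated columns are lower-cased; genotype is mapped to its
    canonical spelling; boolean columns are coerced to 0/1 integers.
    Violations raise :class:`ValidationError` naming the row and column.
    """
    if schema not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")
    out = df.copy()
    for col, allowed in spec["enums"].items():
        vals = out[col].astype(str).str.strip().str.lower()
        bad = ~vals.isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {row}, column {col!r}: value {out[col].iloc[row]!r} "
                f"not in {sorted(allowed)}"
            )
        out[col] = vals
    if "genotype" in out.columns and schema == "cells":
        out["genotype"] = out["genotype"].map(_GENOTYPE_CANON)
    for col in spec["floats"]:
        try:
            out[col] = out[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"column {col!r}: {exc}") from exc
        bad = ~np.isfinite(out[col].to_numpy())
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"row {row}, column {col!r}: non-finite value")
    for col in spec["bools"]:
        vals = out[col].astype(str).str.strip().str.lower()
        bad = ~vals.isin(_BOOL01)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {row}, column {col!r}: {out[col].iloc[row]!r} is not boolean"
            )
        out[col] = vals.map({"0": 0, "1": 1, "false": 0, "true": 1}).astype(int)
    for col in spec.get("ints", []):
        try:
            as_float = out[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"column {col!r}: {exc}") from exc
        if not np.allclose(as_float, np.round(as_float)):
            row = int(np.flatnonzero(~np.isclose(as_float, np.round(as_float)))[0])
            raise ValidationError(f"row {row}, column {col!r}: non-integer count")
        out[col] = as_float.astype(int)
    return out


def _sniff_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a delimited table (TSV or CSV, sniffed)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    logger.info("%s: read %d rows", path.name, len(df))
    return validate_table(df, schema)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as TSV (UTF-8, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    logger.info("%s: wrote %d rows", path.name, len(df))
    return path


def _rosette_cells(spacing: float = 10.0) -> pd.DataFrame:
    """A 7-cell hexagonal clone rosette ringed by untransduced cells."""
    rows = []
    sites = [(0, 0)] + list(sim.HEX_NEIGHBORS)
    for i, s in enumerate(sites):
        x, y = sim.axial_to_xy(s, spacing)
        rows.append(
            {
                "animal_id": "a1", "clone_id": "clone1", "cell_id": f"m{i}",
                "x_um": x, "y_um": y, "layer": "basal", "genotype": "HrasG12V",
                "edu": 0, "brdu": 0, "k10": 0,
            }
        )
    ring = sorted(
        {
            (q + dq, r + dr)
            for q, r in sites
            for dq, dr in sim.HEX_NEIGHBORS
        }
        - set(sites)
    )
    for i, s in enumerate(ring):
        x, y = sim.axial_to_xy(s, spacing)
        rows.append(
            {
                "animal_id": "a1", "clone_id": "", "cell_id": f"w{i}",
                "x_um": x, "y_um": y, "layer": "basal", "genotype": "WT",
                "edu": 0, "brdu": 0, "k10": 0,
            }
        )
    return pd.DataFrame(rows)


def _cfi_events_fixture() -> pd.DataFrame:
    """Deterministic division-event table at the measured fate frequencies.

    100 wild-type events with exactly (29 SR, 44 AD, 27 SD) and 100
    single-mutant events with exactly (48 SR, 42 AD, 10 SD), so the
    derived renewal rates are exactly 0.51 and 0.69.
    """
    def block(context, n_sr, n_ad, n_sd, animal):
        rows = []
        for t, n in (("SR", n_sr), ("AD", n_ad), ("SD", n_sd)):
            d1, d2 = {
                "SR": ("basal", "basal"),
                "AD": ("basal", "suprabasal"),
                "SD": ("suprabasal", "suprabasal"),
            }[t]
            rows += [
                {
                    "animal_id": animal, "clone_id": "", "context": context,
                    "week": 0.0, "daughter1_layer": d1, "daughter2_layer": d2,
                    "daughter1_morph": "unknown", "daughter2_morph": "unknown",
                }
            ] * n
        return rows

    return pd.DataFrame(
        block("wt_distant", 29, 44, 27, "wt1") + block("single_cell", 48, 42, 10, "mut1")
    )


def make_fixtures(kind: str, seed: int = 0) -> pd.DataFrame:
    """Small deterministic datasets used throughout the test suite.

    ``cfi_events``: event table carrying the measured wild-type and
    mutant division-type frequencies exactly.  ``clone_cells``: a 7-cell
    hexagonal rosette clone with its untransduced neighbour ring.
    ``screen_counts``: a simulated screen with two planted strongly
    basal-enriched genes (8-fold, in 5 and 2 hairpins).
    """
    if kind == "cfi_events":
        return _cfi_events_fixture()
    if kind == "clone_cells":
        return _rosette_cells()
    if kind == "screen_counts":
        design = sim.ScreenDesign(
            effects={"gene01": 3.0, "gene02": 3.0},
            effect_shrnas={"gene02": 2},  # gene01: all hairpins; gene02: 2 of 5
        )
        return sim.simulate_screen_counts(design, seed=seed)
    raise ValidationError(f"unknown fixture kind {kind!r}")
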