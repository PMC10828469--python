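"""Sample manifest handling.

A manifest is a CSV with one row per slide: ``slide_id`` (unique),
``age_months`` (positive integer), optional ``group`` and ``treatment``
labels, and ``tile_paths`` — ';'-joined image paths relative to the
manifest file (or absolute).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_manifest", "manifest_tile_paths"]

REQUIRED_COLUMNS = ("slide_id", "age_months", "tile_paths")


def read_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate a slide manifest.

    Rejects duplicate slide ids, non-positive ages, and (by default)
    references to missing image files, naming the offenders.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"slide_id": str}, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest {path} is missing columns {missing_cols}")
    for col in ("group", "treatment"):
        if col not in df.columns:
            df[col] = ""
    dupes = df["slide_id"][df["slide_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate slide_id(s) in manifest: {sorted(set(dupes))}")
    try:
        ages = df["age_months"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-integer age_months in manifest {path}: {exc}") from exc
    bad_age = df.loc[ages <= 0, "slide_id"].tolist()
    if bad_age:
        raise ValueError(f"non-positive age_months for slide(s): {bad_age}")
    df["age_months"] = ages
    if check_paths:
        missing: list[str] = []
        for _, row in df.iterrows():
            for rel in str(row["tile_paths"]).split(";"):
                p = Path(rel)
                if not p.is_absolute():
                    p = path.parent / p
                if not p.exists():
                    missing.append(f"{row['slide_id']}: {rel}")
        if missing:
            raise FileNotFoundError("manifest references missing files: " + "; ".join(missing))
    df.attrs["base_dir"] = str(path.parent)
    return df


def manifest_tile_paths(row: pd.Series, base_dir: str | Path) -> list[Path]:
    """Resolve a row's ';'-joined tile paths against the manifest directory."""
    base = Path(base_dir)
    out = []
    for rel in str(row["tile_paths"]).split(";"):
        p = Path(rel)
        out.append(p if p.is_absolute() else base / p)
    return out
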