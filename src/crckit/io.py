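"""Readers and writers for the tabular formats the pipeline consumes.

All coordinates are 1-based and fully closed (MAF convention).  Mutation
tables are tab-delimited with a configurable column map; lesion matrices
follow the GISTIC lesion-by-sample layout (rows = lesions labelled
``Amp_<cytoband>`` / ``Del_<cytoband>``, columns = samples, cells in
{0, 1, 2} or boolean); clinical tables are CSV; signature references are
96-row TSV matrices with one column per signature.

Tables are returned as pandas DataFrames with canonical column names.
Missing population allele frequencies are kept as 0.0 (absence from the
databases is treated as evidence of rarity, so the variant is retained by
the common-variant filter).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import CONTEXTS_96


class FormatError(ValueError):
    """Malformed input file (missing columns, wrong shape, bad values)."""


#: Canonical mutation-table columns, in output order.
MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "func_class",
    "vaf",
    "depth",
    "alt_reads",
    "trinuc_context",
    "pop_af_1000g",
    "pop_af_exac",
    "oncogenicity",
    "n_neoantigens",
    "is_silent",
]

_REQUIRED_MUTATION_COLUMNS = MUTATION_COLUMNS[:11]

_MUTATION_DEFAULTS = {
    "pop_af_1000g": 0.0,
    "pop_af_exac": 0.0,
    "oncogenicity": "unknown",
    "n_neoantigens": 0,
    "is_silent": False,
}

CLINICAL_COLUMNS = [
    "sample_id",
    "stage",
    "grade",
    "site",
    "msi_high",
    "pole_mutant",
    "os_months",
    "os_event",
]


def _validate_mutation_table(df: pd.DataFrame, source: str) -> pd.DataFrame:
    bad_vaf = pd.to_numeric(df["vaf"], errors="coerce")
    if bad_vaf.isna().any():
        line = int(df.index[bad_vaf.isna()][0]) + 2  # 1-based, after header
        raise FormatError(f"{source}: non-numeric VAF at line {line}")
    df = df.copy()
    df["vaf"] = bad_vaf.astype(float)
    for col in ("pos", "depth", "alt_reads", "n_neoantigens"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
    for col in ("pop_af_1000g", "pop_af_exac"):
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0.0)
    df["is_silent"] = df["is_silent"].astype(bool)
    if (df["pos"] < 1).any():
        raise FormatError(f"{source}: positions must be >= 1 (1-based)")
    if ((df["vaf"] < 0) | (df["vaf"] > 1)).any():
        raise FormatError(f"{source}: VAF outside [0, 1]")
    if (df["alt_reads"] > df["depth"]).any():
        raise FormatError(f"{source}: alt_reads exceeds depth")
    return df[MUTATION_COLUMNS]


def read_mutation_table(
    path: str | Path, dialect: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a MAF-dialect TSV of somatic mutations.

    Parameters
    ----------
    path
        Tab-delimited file with one variant per row.
    dialect
        Optional mapping from file column names to canonical names, for
        MAF files with vendor-specific headers.

    Raises
    ------
    FormatError
        If a required column is absent (the error names it) or a VAF is
        non-numeric (the error carries the 1-based line number).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    if dialect:
        df = df.rename(columns=dialect)
    for col in _REQUIRED_MUTATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    for col, default in _MUTATION_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    return _validate_mutation_table(df, str(path))


def write_mutation_table(table: pd.DataFrame, path: str | Path) -> None:
    table[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_lesion_matrix(path: str | Path) -> pd.DataFrame:
    """Read a GISTIC-style lesion-by-sample matrix into long lesion calls.

    Any nonzero/true cell becomes a call; the direction is parsed from the
    row label prefix (``Amp``/``Del``, case-insensitive, separated by
    ``_``, ``-`` or ``:``).  Returns columns
    ``sample_id, lesion_id, direction, called`` with ``called`` all True.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0)
    calls = []
    for label, row in mat.iterrows():
        direction, lesion_id = _parse_lesion_label(str(label))
        for sample, cell in row.items():
            if bool(cell) and float(cell) != 0.0:
                calls.append((str(sample), lesion_id, direction))
    out = pd.DataFrame(calls, columns=["sample_id", "lesion_id", "direction"])
    out["called"] = True
    return out


def _parse_lesion_label(label: str) -> tuple[str, str]:
    for sep in ("_", "-", ":"):
        if sep in label:
            prefix, rest = label.split(sep, 1)
            lowered = prefix.strip().lower()
            if lowered in ("amp", "amplification"):
                return "amp", rest
            if lowered in ("del", "deletion"):
                return "del", rest
    raise FormatError(
        f"ambiguous lesion label {label!r}: expected 'Amp_<id>' or 'Del_<id>'"
    )


def write_lesion_matrix(
    calls: pd.DataFrame, path: str | Path, samples: list[str] | None = None
) -> None:
    """Write lesion calls back to the wide GISTIC-style layout."""
    if samples is None:
        samples = sorted(calls["sample_id"].unique())
    labels = sorted(
        {(d.capitalize() + "_" + l) for d, l in zip(calls["direction"], calls["lesion_id"])}
    )
    mat = pd.DataFrame(0, index=pd.Index(labels, name="lesion"), columns=samples)
    for _, row in calls.iterrows():
        if row.get("called", True):
            mat.loc[row["direction"].capitalize() + "_" + row["lesion_id"], row["sample_id"]] = 1
    mat.to_csv(path, sep="\t")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    df["msi_high"] = df["msi_high"].astype(bool)
    df["pole_mutant"] = df["pole_mutant"].astype(bool)
    df["os_event"] = df["os_event"].astype(bool)
    df["os_months"] = pd.to_numeric(df["os_months"])
    if (df["os_months"] < 0).any():
        raise FormatError(f"{path}: negative survival time")
    return df[CLINICAL_COLUMNS]


def write_clinical_table(table: pd.DataFrame, path: str | Path) -> None:
    table[CLINICAL_COLUMNS].to_csv(path, index=False)


def read_signature_reference(path: str | Path) -> pd.DataFrame:
    """Read a 96 x K signature reference TSV and renormalize columns.

    Rows are the 96 substitution classes (index labels like ``A[C>T]G``);
    columns are signatures.  Columns are renormalized to sum exactly 1,
    so references stored as percentages or counts are accepted.
    """
    ref = pd.read_csv(path, sep="\t", index_col=0)
    if ref.shape[0] != 96:
        raise FormatError(
            f"{path}: expected 96 context rows, found {ref.shape[0]}"
        )
    missing = set(CONTEXTS_96) - set(ref.index)
    if missing:
        raise FormatError(f"{path}: unrecognized context labels; e.g. missing {sorted(missing)[:3]}")
    ref = ref.loc[CONTEXTS_96].astype(float)
    sums = ref.sum(axis=0)
    if (sums <= 0).any():
        raise FormatError(f"{path}: non-positive signature column sum")
    return ref / sums


def write_signature_reference(ref: pd.DataFrame, path: str | Path) -> None:
    ref.to_csv(path, sep="\t", index_label="context")


def write_results(
    bundle: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config=None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write one TSV per result stage plus a JSON run manifest.

    Output is deterministic: fixed column order (as given), sorted
    manifest keys.  Returns the mapping of stage name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for stage in sorted(bundle):
        p = out_dir / f"{stage}.tsv"
        bundle[stage].to_csv(p, sep="\t", index=False)
        written[stage] = p
    manifest = {
        "stages": sorted(bundle),
        "seed": seed if seed is not None else (config.random_seed if config else None),
        "config": config.to_dict() if config is not None else None,
    }
    mp = out_dir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = mp
    return written
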