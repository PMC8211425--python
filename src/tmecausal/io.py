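"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as TSV (gene id column + one column per sample) or MatrixMarket;
clinical tables as TSV with a configurable column mapping; gene-set
signatures as GMT (name, description, members, tab-separated).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "read_counts",
    "write_counts",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
]


def read_counts(path: str | Path, mtx_genes: str | Path | None = None,
                mtx_samples: str | Path | None = None) -> pd.DataFrame:
    """Read a genes x samples count matrix from TSV or MatrixMarket.

    For ``.mtx`` input, sidecar files listing row (gene) and column (sample)
    names are required, one name per line.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if mtx_genes is None or mtx_samples is None:
            raise ValueError("MatrixMarket counts need gene and sample name files")
        mat = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = Path(mtx_genes).read_text().split()
        samples = Path(mtx_samples).read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    if (df.values < 0).any():
        raise ValueError("count matrix contains negative entries")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


_DEFAULT_COLUMNS = {
    "sample_id": "sample_id",
    "vital_status": "vital_status",
    "os_time": "os_time",
}


def read_clinical(path: str | Path, column_map: dict[str, str] | None = None,
                  os_time_unit: str = "years") -> pd.DataFrame:
    """Read the clinical TSV, renaming columns per ``column_map``
    (canonical name -> file header) and converting survival time to years
    when ``os_time_unit`` is ``"days"`` (the TCGA export dialect)."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in _DEFAULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table lacks required columns: {missing}")
    if os_time_unit == "days":
        df["os_time"] = df["os_time"] / 365.25
    elif os_time_unit != "years":
        raise ValueError(f"unknown os_time_unit {os_time_unit!r}")
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into {set name: member gene ids}."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(members)])
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
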