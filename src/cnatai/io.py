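"""Readers and writers for the pipeline's plain-text formats.

* probe table: TSV, header ``probe_id  chrom  pos  <sample> ...``; chromosome
  tokens "1".."22" and "X" (mapped to 23); values are log2 ratios, blank or
  NA = missing.
* segment file: BED-like TSV with 0-based half-open coordinates,
  ``chrom  start  end  sample_id  n_probes  mean_log2``; means are written at
  full precision so that write-then-read is the identity.
* clinical table: CSV with the ClinicalRecord columns.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalRecord,
    CopyNumberProfile,
    ProbeMap,
    Segment,
    SegmentedProfile,
)

log = logging.getLogger(__name__)

_CHROM_TOKENS = {str(i): i for i in range(1, 23)} | {"X": 23, "x": 23, "23": 23}


def parse_chromosome(token: str) -> int | None:
    """Map a chromosome token to 1-23 (X -> 23); None if unrecognised."""
    token = str(token).strip()
    if token.lower().startswith("chr"):
        token = token[3:]
    return _CHROM_TOKENS.get(token)


def read_probe_table(path: str | Path) -> tuple[ProbeMap, list[CopyNumberProfile]]:
    """Read a probe-level log2-ratio table.

    Rows with unparseable chromosome tokens are dropped (count logged);
    duplicate probe ids raise; non-monotone positions are sorted with a
    warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    if df.empty:
        raise ValueError(f"{path}: empty probe table")
    required = ["probe_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: header must start with {required}")
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate probe_id {dup!r}")

    chrom_num = df["chrom"].map(parse_chromosome)
    bad = chrom_num.isna()
    if bad.any():
        log.warning("%s: dropped %d rows with unparseable chromosome", path, int(bad.sum()))
        df = df[~bad]
        chrom_num = chrom_num[~bad]
    if df.empty:
        raise ValueError(f"{path}: no rows with a recognised chromosome")
    df = df.assign(_chrom=chrom_num.astype(np.int64), _pos=df["pos"].astype(np.int64))

    order = np.lexsort((df["_pos"].to_numpy(), df["_chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(df))):
        log.warning("%s: probes not sorted by (chromosome, position); sorting", path)
        df = df.iloc[order]

    pmap = ProbeMap(
        probe_id=df["probe_id"].to_numpy(dtype=object),
        chrom=df["_chrom"].to_numpy(),
        pos=df["_pos"].to_numpy(),
    )
    sample_cols = [c for c in df.columns if c not in ("probe_id", "chrom", "pos", "_chrom", "_pos")]
    profiles = [
        CopyNumberProfile(sample_id=c, values=df[c].to_numpy(dtype=float)) for c in sample_cols
    ]
    return pmap, profiles


def write_probe_table(
    path: str | Path, probe_map: ProbeMap, profiles: list[CopyNumberProfile]
) -> None:
    cols: dict[str, object] = {
        "probe_id": probe_map.probe_id,
        "chrom": ["X" if c == 23 else str(c) for c in probe_map.chrom],
        "pos": probe_map.pos,
    }
    for p in profiles:
        if len(p.values) != len(probe_map):
            raise ValueError(f"sample {p.sample_id}: values not aligned to probe map")
        cols[p.sample_id] = p.values
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_segments(profiles: list[SegmentedProfile], path: str | Path) -> None:
    """Write BED-like segment TSV (0-based half-open; sorted within sample)."""
    rows = []
    for sp in profiles:
        segs = sorted(sp.segments, key=lambda s: (s.chromosome, s.start_bp))
        prev: Segment | None = None
        for s in segs:
            if prev is not None and s.chromosome == prev.chromosome and s.start_bp <= prev.end_bp:
                raise ValueError(
                    f"sample {sp.sample_id}: overlapping segments on chromosome {s.chromosome}"
                )
            rows.append(
                (s.chromosome, s.start_bp - 1, s.end_bp, sp.sample_id, s.n_probes, s.mean_log2)
            )
            prev = s
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_id", "n_probes", "mean_log2"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_segments(path: str | Path) -> list[SegmentedProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    out: list[SegmentedProfile] = []
    for sid, grp in df.groupby("sample_id", sort=False):
        segs = [
            Segment(
                chromosome=int(r.chrom),
                start_bp=int(r.start) + 1,
                end_bp=int(r.end),
                n_probes=int(r.n_probes),
                mean_log2=float(r.mean_log2),
            )
            for r in grp.itertuples()
        ]
        segs.sort(key=lambda s: (s.chromosome, s.start_bp))
        out.append(SegmentedProfile(sample_id=str(sid), segments=segs))
    return out


_CLINICAL_COLS = [
    "sample_id",
    "age",
    "stage",
    "grade",
    "chemo_response",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
]


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical CSV; blank grade is preserved as missing."""
    df = pd.read_csv(path)
    missing = set(_CLINICAL_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        grade = getattr(row, "grade")
        grade = None if pd.isna(grade) else int(grade)
        try:
            records.append(
                ClinicalRecord(
                    sample_id=str(row.sample_id),
                    age=float(row.age),
                    stage=int(row.stage),
                    grade=grade,
                    chemo_response=str(row.chemo_response),
                    pfs_months=float(row.pfs_months),
                    pfs_event=int(row.pfs_event),
                    os_months=float(row.os_months),
                    os_event=int(row.os_event),
                )
            )
        except ValueError as e:
            raise ValueError(f"{path}: row {i + 2}: {e}") from e
    return records


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "age": r.age,
                "stage": r.stage,
                "grade": "" if r.grade is None else r.grade,
                "chemo_response": r.chemo_response,
                "pfs_months": r.pfs_months,
                "pfs_event": r.pfs_event,
                "os_months": r.os_months,
                "os_event": r.os_event,
            }
            for r in records
        ],
        columns=_CLINICAL_COLS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame (grade as nullable float, NaN missing)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "age": [r.age for r in records],
            "stage": [r.stage for r in records],
            "grade": [np.nan if r.grade is None else r.grade for r in records],
            "chemo_response": [r.chemo_response for r in records],
            "pfs_months": [r.pfs_months for r in records],
            "pfs_event": [r.pfs_event for r in records],
            "os_months": [r.os_months for r in records],
            "os_event": [r.os_event for r in records],
        }
    )
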