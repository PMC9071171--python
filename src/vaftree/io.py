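"""Read-count table file formats and run configuration.

The canonical inference input is a TSV with header ``site_id  r  m``
(2-state) or ``site_id  r  m1  m2  m3`` (4-state): the model consumes only
per-site read counts, so richer formats (VCF) are converted, never used
internally.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from typing import Optional

import numpy as np
import pandas as pd

from .mutsim import ReadCountTable

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "vcf_to_counts",
    "reproducibility_block",
]

_HEADERS_2 = ["site_id", "r", "m"]
_HEADERS_4 = ["site_id", "r", "m1", "m2", "m3"]


def read_counts_tsv(source) -> ReadCountTable:
    """Read a 2-state or 4-state read-count TSV (dialect auto-detected)."""
    df = pd.read_csv(source, sep="\t", dtype={"site_id": str})
    cols = list(df.columns)
    if cols == _HEADERS_2:
        four = False
    elif cols == _HEADERS_4:
        four = True
    else:
        raise ValueError(
            f"unrecognized header {cols}; expected {_HEADERS_2} or {_HEADERS_4}"
        )
    r = df["r"].to_numpy(dtype=np.int64)
    if four:
        m_types = df[["m1", "m2", "m3"]].to_numpy(dtype=np.int64)
        bad = np.nonzero(m_types.sum(axis=1) > r)[0]
    else:
        m = df["m"].to_numpy(dtype=np.int64)
        bad = np.nonzero(m > r)[0]
    if bad.size:
        lines = (bad + 2).tolist()  # header is line 1
        raise ValueError(f"mutant reads exceed total reads on line(s) {lines[:10]}")
    ids = df["site_id"].to_numpy()
    if four:
        return ReadCountTable(r=r, m_types=m_types, site_ids=ids)
    return ReadCountTable(r=r, m=m, site_ids=ids)


def write_counts_tsv(table: ReadCountTable, sink) -> None:
    """Write a read-count table as TSV (lossless round trip)."""
    ids = (
        table.site_ids
        if table.site_ids is not None
        else np.array([f"s{i}" for i in range(table.n_sites)])
    )
    if table.is_four_state:
        df = pd.DataFrame(
            {
                "site_id": ids,
                "r": table.r,
                "m1": table.m_types[:, 0],
                "m2": table.m_types[:, 1],
                "m3": table.m_types[:, 2],
            }
        )
    else:
        df = pd.DataFrame({"site_id": ids, "r": table.r, "m": table.m})
    df.to_csv(sink, sep="\t", index=False)


def vcf_to_counts(
    source: str,
    depth_field: str = "DP",
    alt_field: str = "AD",
    min_depth: int = 8,
) -> ReadCountTable:
    """Convert a VCF to a read-count table (convenience only).

    Per-record total depth comes from FORMAT ``depth_field`` and per-allele
    depths from FORMAT ``alt_field`` of the first sample (falling back to
    INFO for the total).  Multi-allelic records populate the 4-state mutant
    columns; wild type is r minus the summed alt depths.  Records below
    ``min_depth`` are dropped with a logged count.  Upstream calling, CNV
    and purity correction are out of scope: counts are used as given.
    """
    import pysam

    rs, m_types, ids = [], [], []
    dropped = 0
    with pysam.VariantFile(source) as vcf:
        for rec in vcf:
            sample = rec.samples[0] if rec.samples else None
            depth = None
            if sample is not None and depth_field in sample:
                depth = sample[depth_field]
            elif depth_field in rec.info:
                depth = rec.info[depth_field]
            if depth is None:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} lacks depth field {depth_field!r}"
                )
            if sample is None or alt_field not in sample or sample[alt_field] is None:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} lacks allele-depth field "
                    f"{alt_field!r}"
                )
            ad = sample[alt_field]  # (ref, alt1, alt2, ...)
            alts = list(ad[1:4]) + [0] * max(0, 3 - len(ad[1:]))
            depth = int(depth)
            if depth < min_depth:
                dropped += 1
                continue
            rs.append(depth)
            m_types.append([int(a or 0) for a in alts[:3]])
            ids.append(f"{rec.chrom}:{rec.pos}")
    if dropped:
        warnings.warn(
            f"dropped {dropped} record(s) below minimum depth {min_depth}",
            stacklevel=2,
        )
    if not rs:
        return ReadCountTable(
            r=np.zeros(0, dtype=np.int64),
            m_types=np.zeros((0, 3), dtype=np.int64),
            site_ids=np.array([], dtype=object),
        )
    return ReadCountTable(
        r=np.array(rs, dtype=np.int64),
        m_types=np.array(m_types, dtype=np.int64),
        site_ids=np.array(ids, dtype=object),
    )


def reproducibility_block(config, seed: int) -> dict:
    """Version / config-hash / seed block attached to every CLI output."""
    from . import __version__

    if hasattr(config, "__dataclass_fields__"):
        payload = {k: _jsonable(v) for k, v in asdict(config).items()}
    else:
        payload = {k: _jsonable(v) for k, v in dict(config).items()}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    return {
        "version": __version__,
        "config": payload,
        "config_hash": digest,
        "master_seed": int(seed),
    }


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
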