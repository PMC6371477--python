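"""Single-file serialization of cell databases (`.ch` files).

Layout: an 8-byte magic ``CELLHSDB``, a little-endian uint32 format
version, a length-prefixed JSON section table (name, offset, length,
sha256 per section), then the section payloads.  Each section is a
deterministic encoding of a nested structure of dicts, lists, scalars,
bytes and ndarrays: a sorted-key JSON manifest followed by length-prefixed
binary blobs (arrays stored C-contiguous, little-endian).  Serialization is
fully deterministic — saving the same database twice yields byte-identical
files — and every section is verified against its checksum on load, so
truncation or corruption fails with the offending section named.

The compressed raw-count section is decoded into its per-cell compressed
blocks at load time but individual cells are only decompressed when DEG
detection asks for them.
"""

from __future__ import annotations

import hashlib
import json
import struct
from pathlib import Path
from typing import Any

import numpy as np

from .database import FORMAT_VERSION, CellDatabase
from .hashing import BitCodes, HyperplaneSet
from .mih import MultiIndexHash, SubIndex
from .preprocessing import CellPreprocessor

__all__ = ["save_db", "load_db", "db_info"]

MAGIC = b"CELLHSDB"


# -- generic deterministic object encoding --------------------------------


def _encode_obj(obj: Any) -> bytes:
    blobs: list[bytes] = []

    def walk(o):
        if isinstance(o, np.ndarray):
            arr = np.ascontiguousarray(o)
            dt = arr.dtype.newbyteorder("<")
            blobs.append(arr.astype(dt, copy=False).tobytes())
            return {
                "__array__": len(blobs) - 1,
                "dtype": dt.str,
                "shape": list(arr.shape),
            }
        if isinstance(o, (bytes, bytearray)):
            blobs.append(bytes(o))
            return {"__bytes__": len(blobs) - 1}
        if isinstance(o, dict):
            return {str(k): walk(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [walk(v) for v in o]
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if o is None or isinstance(o, (str, int, float, bool)):
            return o
        raise TypeError(f"cannot serialize object of type {type(o).__name__}")

    manifest = json.dumps(walk(obj), sort_keys=True, separators=(",", ":")).encode()
    out = [struct.pack("<Q", len(manifest)), manifest, struct.pack("<I", len(blobs))]
    for b in blobs:
        out.append(struct.pack("<Q", len(b)))
        out.append(b)
    return b"".join(out)


def _decode_obj(data: bytes) -> Any:
    (mlen,) = struct.unpack_from("<Q", data, 0)
    manifest = json.loads(data[8 : 8 + mlen])
    pos = 8 + mlen
    (n_blobs,) = struct.unpack_from("<I", data, pos)
    pos += 4
    blobs = []
    for _ in range(n_blobs):
        (blen,) = struct.unpack_from("<Q", data, pos)
        pos += 8
        blobs.append(data[pos : pos + blen])
        pos += blen

    def walk(o):
        if isinstance(o, dict):
            if "__array__" in o:
                arr = np.frombuffer(blobs[o["__array__"]], dtype=np.dtype(o["dtype"]))
                return arr.reshape(o["shape"]).copy()
            if "__bytes__" in o:
                return blobs[o["__bytes__"]]
            return {k: walk(v) for k, v in o.items()}
        if isinstance(o, list):
            return [walk(v) for v in o]
        return o

    return walk(manifest)


# -- database <-> section structures --------------------------------------


def _subindex_state(b: SubIndex) -> dict:
    return {
        "s": b.s,
        "filled": b.filled,
        "word_rank": b.word_rank,
        "offsets": b.offsets,
        "buckets": b.buckets,
    }


def _sections_from_db(db: CellDatabase) -> dict[str, Any]:
    prep = db.preprocessor_
    sections: dict[str, Any] = {
        "config": {
            "params": {
                k: (list(v) if isinstance(v, (tuple,)) else v)
                for k, v in db.get_params().items()
            },
            "build_seed": db.build_seed_,
        },
        "preprocessor": {
            "selected_genes": list(prep.selected_genes_),
            "feature_means": prep.feature_means_,
            "feature_sds": prep.feature_sds_,
            "projection": prep.projection_,
            "singular_values": prep.singular_values_,
            "n_features_in": prep.n_features_in_,
        },
        "hashes": [
            {
                "normals": H.normals,
                "rng_seed": H.rng_seed,
                "orthogonalized": H.orthogonalized,
                "code_words": mih.codes.words,
                "n_bits": mih.codes.n_bits,
                "bit_ranges": [list(r) for r in mih.bit_ranges],
                "blocks": [_subindex_state(b) for b in mih.blocks],
            }
            for H, mih in db.hashes_
        ],
        "metadata": {
            "cell_names": list(db.cell_names_),
            "labels": None if db.labels_ is None else [str(x) for x in db.labels_],
        },
    }
    if db.raw_store_ is not None:
        rs = db.raw_store_
        sections["counts"] = {
            "gene_names": rs.gene_names,
            "cell_names": rs.cell_names,
            "blocks": rs.blocks,
            "totals": rs.totals,
        }
    return sections


def _db_from_sections(sections: dict[str, Any]) -> CellDatabase:
    params = dict(sections["config"]["params"])
    db = CellDatabase(**params)

    p = sections["preprocessor"]
    prep = CellPreprocessor(
        min_features_fraction=params["min_features_fraction"],
        count_transform=params["count_transform"],
        n_dims=params["n_dims"],
        keep_genes=params["keep_genes"],
        drop_genes=params["drop_genes"],
        scale_factor=params["scale_factor"],
        random_state=sections["config"]["build_seed"],
    )
    prep.selected_genes_ = list(p["selected_genes"])
    prep.feature_means_ = p["feature_means"]
    prep.feature_sds_ = p["feature_sds"]
    prep.projection_ = p["projection"]
    prep.singular_values_ = p["singular_values"]
    prep.n_features_in_ = int(p["n_features_in"])

    hashes = []
    for h in sections["hashes"]:
        H = HyperplaneSet(
            normals=h["normals"],
            rng_seed=int(h["rng_seed"]),
            orthogonalized=bool(h["orthogonalized"]),
        )
        codes = BitCodes(words=h["code_words"], n_bits=int(h["n_bits"]))
        blocks = [
            SubIndex(
                s=int(b["s"]),
                filled=b["filled"],
                word_rank=b["word_rank"],
                offsets=b["offsets"],
                buckets=b["buckets"],
            )
            for b in h["blocks"]
        ]
        mih = MultiIndexHash(
            codes=codes,
            blocks=blocks,
            bit_ranges=[tuple(r) for r in h["bit_ranges"]],
        )
        hashes.append((H, mih))

    db.preprocessor_ = prep
    db.hashes_ = hashes
    db.cell_names_ = list(sections["metadata"]["cell_names"])
    labels = sections["metadata"]["labels"]
    db.labels_ = None if labels is None else np.asarray(labels)
    db.build_seed_ = int(sections["config"]["build_seed"])
    db.format_version_ = FORMAT_VERSION
    if "counts" in sections:
        from .deg import CompressedCounts

        c = sections["counts"]
        db.raw_store_ = CompressedCounts(
            gene_names=list(c["gene_names"]),
            cell_names=list(c["cell_names"]),
            blocks=list(c["blocks"]),
            totals=c["totals"],
        )
    else:
        db.raw_store_ = None
    return db


# -- file container --------------------------------------------------------


def save_db(db: CellDatabase, path: str | Path) -> None:
    """Serialize a fitted database to a single checksummed `.ch` file."""
    sections = _sections_from_db(db)
    encoded = {name: _encode_obj(obj) for name, obj in sections.items()}
    table = []
    offset = 0
    for name in sorted(encoded):
        data = encoded[name]
        table.append(
            {
                "name": name,
                "offset": offset,
                "length": len(data),
                "sha256": hashlib.sha256(data).hexdigest(),
            }
        )
        offset += len(data)
    table_json = json.dumps(table, sort_keys=True, separators=(",", ":")).encode()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<I", FORMAT_VERSION))
        fh.write(struct.pack("<Q", len(table_json)))
        fh.write(table_json)
        for name in sorted(encoded):
            fh.write(encoded[name])


def _read_container(path: str | Path) -> dict[str, bytes]:
    path = Path(path)
    raw = path.read_bytes()
    if raw[:8] != MAGIC:
        raise ValueError(f"{path} is not a cellhash database file")
    (version,) = struct.unpack_from("<I", raw, 8)
    if version != FORMAT_VERSION:
        raise ValueError(
            f"unsupported database format version {version} "
            f"(this build supports {FORMAT_VERSION})"
        )
    (tlen,) = struct.unpack_from("<Q", raw, 12)
    table = json.loads(raw[20 : 20 + tlen])
    base = 20 + tlen
    sections = {}
    for entry in table:
        start = base + entry["offset"]
        data = raw[start : start + entry["length"]]
        if (
            len(data) != entry["length"]
            or hashlib.sha256(data).hexdigest() != entry["sha256"]
        ):
            raise ValueError(
                f"checksum mismatch in section {entry['name']!r}: "
                "file is truncated or corrupted"
            )
        sections[entry["name"]] = data
    return sections


def load_db(path: str | Path) -> CellDatabase:
    """Load a `.ch` database; raw counts stay compressed until requested."""
    raw_sections = _read_container(path)
    sections = {name: _decode_obj(data) for name, data in raw_sections.items()}
    return _db_from_sections(sections)


def db_info(path: str | Path) -> dict:
    """Summary of a database file without fully loading the count store."""
    db = load_db(path)
    H, mih = db.hashes_[0]
    return {
        "n_cells": mih.n_codes,
        "n_selected_genes": len(db.preprocessor_.selected_genes_),
        "n_dims": db.preprocessor_.projection_.shape[0],
        "n_bits": mih.n_bits,
        "n_hashes": len(db.hashes_),
        "has_labels": db.labels_ is not None,
        "has_counts": db.raw_store_ is not None,
        "format_version": db.format_version_,
    }
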