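"""End-to-end database scan: filter with phase 1, rank with phase 2.

The pipeline mirrors a filter-and-refine search:

1. load the precomputed database cache (or build it from a directory of
   PDB files);
2. score the query's reduced SSE chain against every database chain
   (phase 1, linear space, query profile);
3. qualify chains with Score(Q,D)/Score(Q,Q) ≥ Q_t — Q_t = 0 turns the
   filter off and every chain passes;
4. align descriptor chains of the survivors (phase 2) and rank by that
   Score, ties broken by id;
5. for the top M hits, backtrack the residue-level alignment and
   superpose the aligned Cα pairs (Kabsch) for the report.

The cache stores per-chain records (id, reduced chain, descriptor
chain, Cα coordinates) sorted ascending by chain length; scan results
are independent of that order and of the zero padding used by the
blocked iteration view.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from .align_core import AlignmentPath, GapPenalties
from .descriptors import (
    DescriptorChain,
    ReducedChain,
    ResidueDescriptor,
    SERegion,
    build_descriptor_chain,
    reduce_chain,
)
from .phase1 import DEFAULT_GAPS1, build_phase1_profile, phase1_score, phase1_self_score
from .phase2 import DEFAULT_GAPS2, Phase2Weights, phase2_align, phase2_score
from .structure_io import CalphaTrace, SSEType, load_trace
from .superpose import SuperpositionResult, rmsd_of_path

__all__ = [
    "SearchParams",
    "Hit",
    "ChainRecord",
    "DatabaseCache",
    "qualifies",
    "build_database",
    "load_database",
    "search",
    "render_alignment",
]

_MAGIC = b"SSDB"
_VERSION = 1
_BLOCK = 32  # chains per padded block in the blocked iteration view


class StaleCacheError(ValueError):
    """Cache file has a different format version; rebuild required."""


class DegenerateQueryError(ValueError):
    """Query self-score is 0; the ratio filter is undefined (use q_t=0)."""


@dataclass(frozen=True)
class SearchParams:
    """Tunable knobs of one database scan."""

    q_t: float = 0.2  # qualification threshold in [0, 1]
    top_m: int = 10  # hits that get alignment paths + superposition
    gaps1: GapPenalties = DEFAULT_GAPS1
    gaps2: GapPenalties = DEFAULT_GAPS2
    weights: Phase2Weights = field(default_factory=Phase2Weights)

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_t <= 1.0):
            raise ValueError("q_t must lie in [0, 1]")
        if self.top_m < 1:
            raise ValueError("top_m must be positive")


@dataclass
class Hit:
    """One database chain's scores in a scan."""

    db_id: str
    phase1_score: float
    ratio: float  # Score^QD / Score^QQ
    qualified: bool
    phase2_score: Optional[float] = None  # present iff qualified
    rank: Optional[int] = None  # 1-based, qualified hits only
    path: Optional[AlignmentPath] = None  # top-M hits only
    superposition: Optional[SuperpositionResult] = None  # top-M, ≥3 pairs


@dataclass(frozen=True)
class ChainRecord:
    """One database chain: trace + both alignment representations."""

    id: str
    trace: CalphaTrace
    reduced: ReducedChain
    descriptors: DescriptorChain

    def __len__(self) -> int:
        return len(self.descriptors)


@dataclass
class DatabaseCache:
    """In-memory database, records sorted ascending by chain length."""

    records: list[ChainRecord]
    block_size: int = _BLOCK

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ChainRecord]:
        return iter(self.records)

    def iter_blocks(self) -> Iterator[list[ChainRecord]]:
        """Yield records in blocks of ``block_size`` chains.

        Within a block all descriptor arrays can be zero-padded to the
        longest member (see :meth:`padded_features`); scores never
        depend on that padding.
        """
        for k in range(0, len(self.records), self.block_size):
            yield self.records[k : k + self.block_size]

    @staticmethod
    def padded_features(block: list[ChainRecord]) -> dict[str, np.ndarray]:
        """Columnar zero-padded feature arrays for one block."""
        width = max(len(r) for r in block)
        c_len = np.zeros((len(block), width))
        gamma = np.zeros((len(block), width))
        for i, rec in enumerate(block):
            c_len[i, : len(rec)] = rec.descriptors.c_lens()
            gamma[i, : len(rec)] = rec.descriptors.gammas()
        return {"c_len": c_len, "gamma": gamma}


def qualifies(score_qd: float, score_qq: float, q_t: float) -> bool:
    """Qualification rule Score^QD / Score^QQ ≥ Q_t (inclusive)."""
    if score_qq <= 0.0:
        raise DegenerateQueryError(
            "degenerate query: self-score is 0; rerun with q_t = 0 for a full scan"
        )
    return score_qd / score_qq >= q_t


# ---------------------------------------------------------------- cache I/O

_SSE_BYTE = {SSEType.H: 0, SSEType.E: 1, SSEType.L: 2}
_BYTE_SSE = {v: k for k, v in _SSE_BYTE.items()}


def _pack_record(rec: ChainRecord) -> bytes:
    out = bytearray()
    rid = rec.id.encode()
    chain_id = rec.trace.chain_id.encode()[:1] or b"A"
    out += struct.pack("<H", len(rid)) + rid + chain_id
    out += struct.pack("<I", len(rec.reduced))
    for region in rec.reduced.regions:
        out += struct.pack("<BI", _SSE_BYTE[region.sse], region.length)
    n = len(rec)
    out += struct.pack("<I", n)
    out += rec.descriptors.c_lens().astype("<f8").tobytes()
    out += rec.descriptors.gammas().astype("<f8").tobytes()
    out += bytes(_SSE_BYTE[s] for s in rec.trace.sse)
    out += "".join(rec.trace.residues).encode()
    out += np.asarray(rec.trace.seq_ids, dtype="<i4").tobytes()
    out += rec.trace.coords.astype("<f8").tobytes()
    return bytes(out)


def _unpack_record(buf: memoryview, off: int) -> tuple[ChainRecord, int]:
    (id_len,) = struct.unpack_from("<H", buf, off)
    off += 2
    rid = bytes(buf[off : off + id_len]).decode()
    off += id_len
    chain_id = bytes(buf[off : off + 1]).decode()
    off += 1
    (n_regions,) = struct.unpack_from("<I", buf, off)
    off += 4
    regions = []
    for _ in range(n_regions):
        code, length = struct.unpack_from("<BI", buf, off)
        off += 5
        regions.append(SERegion(_BYTE_SSE[code], length))
    (n,) = struct.unpack_from("<I", buf, off)
    off += 4
    if n < 1:
        raise ValueError("corrupt cache: empty-chain record")
    c_len = np.frombuffer(buf, "<f8", n, off).copy()
    off += 8 * n
    gamma = np.frombuffer(buf, "<f8", n, off).copy()
    off += 8 * n
    sse = [_BYTE_SSE[b] for b in bytes(buf[off : off + n])]
    off += n
    residues = list(bytes(buf[off : off + n]).decode())
    off += n
    seq_ids = np.frombuffer(buf, "<i4", n, off).tolist()
    off += 4 * n
    coords = np.frombuffer(buf, "<f8", 3 * n, off).copy().reshape(n, 3)
    off += 24 * n
    trace = CalphaTrace(
        structure_id=rid,
        chain_id=chain_id,
        coords=coords,
        residues=residues,
        sse=sse,
        seq_ids=seq_ids,
    )
    descs = tuple(
        ResidueDescriptor(float(c_len[i]), float(gamma[i]), sse[i], residues[i])
        for i in range(n)
    )
    rec = ChainRecord(
        id=rid,
        trace=trace,
        reduced=ReducedChain(id=rid, regions=tuple(regions)),
        descriptors=DescriptorChain(id=rid, descriptors=descs),
    )
    return rec, off


def record_from_trace(rid: str, trace: CalphaTrace) -> ChainRecord:
    """Build both representations of one parsed chain under one id."""
    import dataclasses

    trace = dataclasses.replace(trace, structure_id=rid)
    descriptors = dataclasses.replace(build_descriptor_chain(trace), id=rid)
    reduced = dataclasses.replace(reduce_chain(descriptors), id=rid)
    return ChainRecord(id=rid, trace=trace, reduced=reduced, descriptors=descriptors)


def save_database(db: DatabaseCache, path) -> None:
    """Write the cache: magic, version, block size, count, records."""
    out = bytearray()
    out += _MAGIC + struct.pack("<BBI", _VERSION, db.block_size, len(db.records))
    for rec in db.records:
        out += _pack_record(rec)
    Path(path).write_bytes(bytes(out))


def build_database(pdb_dir, out=None) -> DatabaseCache:
    """Parse every chain of every ``*.pdb`` file under a directory.

    Unparseable chains are skipped with a warning.  Records are sorted
    ascending by residue count (ties by id); if ``out`` is given the
    cache is also written there.  Raises ``ValueError`` when no chain
    parses.
    """
    import gemmi

    records: list[ChainRecord] = []
    for path in sorted(Path(pdb_dir).glob("*.pdb")):
        text = path.read_text()
        try:
            chain_ids = [ch.name for ch in gemmi.read_pdb_string(text)[0]]
        except Exception as exc:
            warnings.warn(f"skipping {path.name}: {exc}")
            continue
        for cid in dict.fromkeys(chain_ids):
            try:
                trace = load_trace(text, cid)
            except Exception as exc:
                warnings.warn(f"skipping {path.name} chain {cid}: {exc}")
                continue
            rid = f"{path.stem}_{cid}"
            records.append(record_from_trace(rid, trace))
    if not records:
        raise ValueError("empty database: no parseable chains found")
    records.sort(key=lambda r: (len(r), r.id))
    db = DatabaseCache(records=records)
    if out is not None:
        save_database(db, out)
    return db


def load_database(path) -> DatabaseCache:
    """Read a cache file written by :func:`save_database`.

    Raises ``StaleCacheError`` on a version mismatch (the cache must be
    rebuilt whenever the format or the source directory changes) and
    ``ValueError`` on truncation/corruption.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 10 or raw[:4] != _MAGIC:
        raise ValueError("not a database cache file")
    version, block_size, count = struct.unpack_from("<BBI", raw, 4)
    if version != _VERSION:
        raise StaleCacheError(
            f"stale cache (format v{version}, expected v{_VERSION}): rebuild required"
        )
    buf = memoryview(raw)
    off = 10
    records = []
    try:
        for _ in range(count):
            rec, off = _unpack_record(buf, off)
            records.append(rec)
    except (struct.error, IndexError, ValueError, KeyError, UnicodeDecodeError) as exc:
        raise ValueError(f"truncated or corrupt cache: {exc}") from exc
    if off != len(raw):
        raise ValueError("truncated or corrupt cache: trailing bytes")
    return DatabaseCache(records=records, block_size=block_size)


# ------------------------------------------------------------------- search


def search(
    query: CalphaTrace,
    db: DatabaseCache,
    params: SearchParams = SearchParams(),
    align: bool = True,
    include_unqualified: bool = False,
) -> list[Hit]:
    """Scan the database for chains similar to the query.

    Returns qualified hits ranked by phase-2 Score (descending, ties by
    id ascending).  The ``params.top_m`` leading hits carry a
    backtracked alignment path and, when ≥ 3 Cα pairs align, a Kabsch
    superposition (skipped when ``align=False``).  With
    ``include_unqualified=True`` the filtered-out chains are appended
    after the ranking, ordered by ratio.
    """
    if len(query) == 0:
        raise ValueError("empty query trace")
    if len(db) == 0:
        raise ValueError("empty database")
    q_desc = build_descriptor_chain(query)
    q_reduced = reduce_chain(q_desc)
    profile = build_phase1_profile(q_reduced)
    score_qq = phase1_self_score(q_reduced, params.gaps1)
    if score_qq <= 0.0 and params.q_t > 0.0:
        raise DegenerateQueryError(
            "degenerate query: self-score is 0; rerun with q_t = 0 for a full scan"
        )

    hits: list[Hit] = []
    for rec in db:
        s1 = phase1_score(q_reduced, rec.reduced, params.gaps1, profile=profile).score
        ratio = s1 / score_qq if score_qq > 0.0 else 0.0
        ok = ratio >= params.q_t if score_qq > 0.0 else params.q_t == 0.0
        hits.append(Hit(db_id=rec.id, phase1_score=s1, ratio=ratio, qualified=ok))

    by_id = {rec.id: rec for rec in db}
    ranked = [h for h in hits if h.qualified]
    for h in ranked:
        h.phase2_score = phase2_score(
            q_desc, by_id[h.db_id].descriptors, params.gaps2, params.weights
        ).score
    ranked.sort(key=lambda h: (-h.phase2_score, h.db_id))
    for rank, h in enumerate(ranked, start=1):
        h.rank = rank
        if align and rank <= params.top_m:
            h.path = phase2_align(
                q_desc, by_id[h.db_id].descriptors, params.gaps2, params.weights
            )
            if len(h.path.aligned_pairs()) >= 3:
                try:
                    h.superposition = rmsd_of_path(h.path, query, by_id[h.db_id].trace)
                except ValueError:
                    h.superposition = None

    if include_unqualified:
        rest = sorted(
            (h for h in hits if not h.qualified), key=lambda h: (-h.ratio, h.db_id)
        )
        return ranked + rest
    return ranked


# ------------------------------------------------------------------ report

_BLOCK_WIDTH = 60


def render_alignment(
    hit: Hit, query: CalphaTrace, db_rec: ChainRecord, width: int = _BLOCK_WIDTH
) -> str:
    """Human-readable block report of one hit's residue-level alignment.

    Five lines per block — query residues, query SSE, match marks
    (``|`` identity, ``:`` same SSE, space otherwise, ``-`` under
    gaps), db SSE, db residues — preceded by the similarity measures.
    """
    if hit.path is None:
        raise ValueError("hit has no alignment path; rerun search with align=True")
    qline, mline, dline, qsse, dsse = [], [], [], [], []
    for qi, dj in hit.path.pairs:
        qc = query.residues[qi] if qi is not None else "-"
        dc = db_rec.trace.residues[dj] if dj is not None else "-"
        qs = query.sse[qi].value if qi is not None else "-"
        ds = db_rec.trace.sse[dj].value if dj is not None else "-"
        if qi is None or dj is None:
            m = "-"
        elif qc == dc:
            m = "|"
        elif qs == ds:
            m = ":"
        else:
            m = " "
        qline.append(qc)
        dline.append(dc)
        qsse.append(qs)
        dsse.append(ds)
        mline.append(m)

    head = [
        f"Query: {query.structure_id} chain {query.chain_id} ({len(query)} residues)",
        f"Hit:   {hit.db_id} ({len(db_rec)} residues)  rank {hit.rank}",
        f"Score (phase 2): {hit.phase2_score:.4f}",
        f"Phase-1 score:   {hit.phase1_score:.4f}  ratio {hit.ratio:.4f}",
    ]
    if hit.superposition is not None:
        head.append(
            f"RMSD: {hit.superposition.rmsd:.4f} A over {hit.superposition.n_pairs} "
            "aligned Calpha pairs"
        )
    blocks = []
    for k in range(0, len(qline), width):
        s = slice(k, k + width)
        blocks.append(
            "\n".join(
                [
                    "Q   " + "".join(qline[s]),
                    "sse " + "".join(qsse[s]),
                    "    " + "".join(mline[s]),
                    "sse " + "".join(dsse[s]),
                    "D   " + "".join(dline[s]),
                ]
            )
        )
    return "\n".join(head) + "\n\n" + "\n\n".join(blocks) + "\n"
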