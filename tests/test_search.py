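"""Database cache, qualification filter, ranking and reporting."""

import dataclasses
import struct

import numpy as np
import pytest

from conftest import random_rotation
from strucsim.fixtures import FixtureSpec, make_trace, write_database, write_pdb
from strucsim.search import (
    DatabaseCache,
    DegenerateQueryError,
    SearchParams,
    StaleCacheError,
    build_database,
    load_database,
    qualifies,
    render_alignment,
    save_database,
    search,
)
from strucsim.structure_io import SSEType

H, E, L = SSEType.H, SSEType.E, SSEType.L


@pytest.fixture(scope="module")
def small_db(tmp_path_factory):
    root = tmp_path_factory.mktemp("db")
    write_database(root / "pdb", n_chains=20, seed=77)
    return build_database(root / "pdb", out=root / "cache.bin"), root


class TestQualifies:
    @pytest.mark.parametrize(
        "qd, qq, qt, expected",
        [
            (2.5, 2.5, 0.2, True),
            (0.0, 2.5, 0.2, False),
            (0.5, 2.5, 0.2, True),  # ratio exactly at threshold, inclusive
        ],
    )
    def test_threshold_rule(self, qd, qq, qt, expected):
        assert qualifies(qd, qq, qt) is expected

    def test_degenerate_denominator(self):
        with pytest.raises(DegenerateQueryError):
            qualifies(1.0, 0.0, 0.2)


class TestCache:
    def test_build_counts_and_sorted_order(self, small_db):
        db, _ = small_db
        assert len(db) == 20
        lengths = [len(rec) for rec in db]
        assert lengths == sorted(lengths)

    def test_rebuild_after_adding_a_file(self, small_db, tmp_path):
        db, root = small_db
        import shutil

        new_dir = tmp_path / "pdb2"
        shutil.copytree(root / "pdb", new_dir)
        extra = make_trace(
            FixtureSpec(seed=123, n_residues=25, sse_layout=((H, 10), (L, 5), (E, 10)))
        )
        (new_dir / "EXTRA.pdb").write_text(write_pdb(extra))
        assert len(build_database(new_dir)) == 21

    def test_write_load_roundtrip_identity(self, small_db):
        db, root = small_db
        loaded = load_database(root / "cache.bin")
        assert len(loaded) == len(db)
        for a, b in zip(db, loaded):
            assert a.id == b.id
            assert a.reduced == b.reduced
            assert a.descriptors == b.descriptors
            assert np.array_equal(a.trace.coords, b.trace.coords)
            assert a.trace.residues == b.trace.residues
            assert a.trace.seq_ids == b.trace.seq_ids

    def test_truncated_file_rejected(self, small_db, tmp_path):
        _, root = small_db
        raw = (root / "cache.bin").read_bytes()
        bad = tmp_path / "trunc.bin"
        bad.write_bytes(raw[: len(raw) // 2])
        with pytest.raises(ValueError, match="truncat|corrupt"):
            load_database(bad)

    def test_version_bump_is_stale(self, small_db, tmp_path):
        _, root = small_db
        raw = bytearray((root / "cache.bin").read_bytes())
        raw[4] = 99  # version byte
        bad = tmp_path / "stale.bin"
        bad.write_bytes(bytes(raw))
        with pytest.raises(StaleCacheError, match="rebuild"):
            load_database(bad)

    def test_not_a_cache_file(self, tmp_path):
        p = tmp_path / "junk.bin"
        p.write_bytes(b"PDB!" + b"\x00" * 20)
        with pytest.raises(ValueError, match="not a database cache"):
            load_database(p)

    def test_empty_directory_rejected(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(ValueError, match="empty database"):
            build_database(tmp_path / "empty")

    def test_block_iteration_covers_all_records(self, small_db):
        db, _ = small_db
        blocked = [rec.id for block in db.iter_blocks() for rec in block]
        assert blocked == [rec.id for rec in db]
        feats = DatabaseCache.padded_features(db.records[:5])
        width = max(len(r) for r in db.records[:5])
        assert feats["c_len"].shape == (5, width)


class TestSearch:
    def test_exact_copy_ranks_first_with_ratio_one(self, small_db):
        db, _ = small_db
        src = db.records[10]
        hits = search(src.trace, db, SearchParams(q_t=0.2, top_m=3))
        assert hits[0].db_id == src.id
        assert hits[0].ratio == pytest.approx(1.0)
        assert hits[0].rank == 1

    def test_rigid_copy_rank1_ratio1_rmsd_tiny(self, small_db, rng):
        db, _ = small_db
        src = db.records[15]
        rot = random_rotation(rng)
        moved = dataclasses.replace(
            src.trace, coords=src.trace.coords @ rot.T + np.array([8.0, -2.0, 5.0])
        )
        hits = search(moved, db, SearchParams(q_t=0.2, top_m=3))
        top = hits[0]
        assert top.db_id == src.id
        assert top.ratio == pytest.approx(1.0)
        assert top.superposition is not None
        assert top.superposition.rmsd <= 1e-6

    def test_qt_zero_qualifies_everything(self, small_db):
        db, _ = small_db
        hits = search(db.records[0].trace, db, SearchParams(q_t=0.0, top_m=1), align=False)
        assert len(hits) == len(db)

    def test_qt_one_on_dissimilar_chains_empty_ranking(self, small_db):
        db, _ = small_db
        query = make_trace(
            FixtureSpec(seed=5, n_residues=40, sse_layout=((H, 10), (E, 10), (H, 10), (E, 10)))
        )
        hits = search(query, db, SearchParams(q_t=1.0, top_m=5), align=False)
        assert all(h.ratio == pytest.approx(1.0) for h in hits)  # only perfect survives

    def test_filtering_monotone_in_threshold(self, small_db):
        db, _ = small_db
        query = db.records[8].trace
        sizes = []
        prev_sets = None
        for qt in (0.01, 0.2, 0.4, 0.6, 0.8):
            hits = search(query, db, SearchParams(q_t=qt, top_m=1), align=False)
            ids = {h.db_id for h in hits}
            if prev_sets is not None:
                assert ids <= prev_sets
            prev_sets = ids
            sizes.append(len(ids))
        assert sizes == sorted(sizes, reverse=True)

    def test_results_independent_of_db_order(self, small_db, rng):
        db, _ = small_db
        query = db.records[3].trace
        shuffled = DatabaseCache(records=list(rng.permutation(np.array(db.records, dtype=object))))
        a = search(query, db, SearchParams(q_t=0.2, top_m=4))
        b = search(query, shuffled, SearchParams(q_t=0.2, top_m=4))
        assert [(h.db_id, h.rank) for h in a] == [(h.db_id, h.rank) for h in b]
        assert [h.phase2_score for h in a] == pytest.approx([h.phase2_score for h in b])

    def test_include_unqualified_appends_rest(self, small_db):
        db, _ = small_db
        query = db.records[5].trace
        all_hits = search(query, db, SearchParams(q_t=0.6, top_m=1), align=False,
                          include_unqualified=True)
        assert len(all_hits) == len(db)
        ranked = [h for h in all_hits if h.qualified]
        rest = all_hits[len(ranked):]
        assert all(h.phase2_score is None and h.rank is None for h in rest)


class TestRenderAlignment:
    def test_self_alignment_match_line_all_identities(self, small_db):
        db, _ = small_db
        src = db.records[4]
        hits = search(src.trace, db, SearchParams(q_t=0.2, top_m=1))
        report = render_alignment(hits[0], src.trace, src)
        match_lines = [ln[4:] for ln in report.splitlines() if ln.startswith("    ")]
        assert set("".join(match_lines)) == {"|"}
        assert f"{hits[0].phase2_score:.4f}" in report

    def test_gap_rendered_as_dash(self, small_db):
        db, _ = small_db
        src = db.records[12]
        # delete two interior residues from the query copy
        tr = src.trace
        keep = [i for i in range(len(tr)) if i not in (10, 11)]
        query = dataclasses.replace(
            tr,
            coords=tr.coords[keep],
            residues=[tr.residues[i] for i in keep],
            sse=[tr.sse[i] for i in keep],
            seq_ids=[tr.seq_ids[i] for i in keep],
        )
        hits = search(query, db, SearchParams(q_t=0.2, top_m=1))
        top = hits[0]
        assert top.db_id == src.id
        report = render_alignment(top, query, src)
        if top.path.n_gaps():
            assert "-" in report


class TestCLI:
    def test_build_and_search_roundtrip(self, small_db, tmp_path):
        from click.testing import CliRunner

        from strucsim.cli import main

        _, root = small_db
        runner = CliRunner()
        cache = tmp_path / "cli_cache.bin"
        res = runner.invoke(main, ["build-db", str(root / "pdb"), "-o", str(cache)])
        assert res.exit_code == 0, res.output
        assert "cached 20 chains" in res.output

        query_pdb = sorted((root / "pdb").glob("*.pdb"))[0]
        out_json = tmp_path / "hits.json"
        out_rep = tmp_path / "report.txt"
        res = runner.invoke(
            main,
            [
                "search", str(query_pdb), "--chain", "A", "--db", str(cache),
                "--qt", "0.2", "--top", "3",
                "--json", str(out_json), "--report", str(out_rep),
            ],
        )
        assert res.exit_code == 0, res.output
        import json

        hits = json.loads(out_json.read_text())
        assert hits[0]["rank"] == 1
        assert hits[0]["ratio"] == pytest.approx(1.0)
        assert "Score" in out_rep.read_text()
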