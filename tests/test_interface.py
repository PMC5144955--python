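"""Format round-trips, run configuration, and the command-line interface."""

import json

import pytest
from click.testing import CliRunner

from synbreak import io
from synbreak.cli import main
from synbreak.config import RunConfig
from synbreak.core import BreakpointInterval, EventType, RearrangementEvent
from synbreak.fixtures import (
    PAPER_TIP_STATES,
    PAPER_TREE,
    paper_genomes,
    paper_profiles,
    run_paper_demo,
    urartu_4al_junction,
)
from synbreak.junctions import scan_tracts, density_profile


class TestRoundTrips:
    def test_genomes_tsv(self, tmp_path, genomes):
        path = tmp_path / "genomes.tsv"
        io.write_genomes_tsv(genomes.values(), path)
        back = io.read_genomes_tsv(path)
        assert set(back) == set(genomes)
        for taxon, g in genomes.items():
            for arm_id, arm in g.arms.items():
                assert back[taxon].arms[arm_id].genes == arm.genes

    def test_event_log_json(self, tmp_path):
        log = {
            "carrier": [
                RearrangementEvent(EventType.RECIPROCAL_TRANSLOCATION, ("1L", "2L"), (3, 4)),
                RearrangementEvent(EventType.TRANSPOSITION, ("1L",), (0,), payload="g"),
            ],
            "sister": [],
        }
        path = tmp_path / "events.json"
        io.write_event_log(log, path)
        assert io.read_event_log(path) == log

    def test_profile_tsv(self, tmp_path):
        table = paper_profiles()["5DL"]
        path = tmp_path / "profile.tsv"
        io.write_profile_tsv(table, path)
        back = io.read_profile_tsv(path)
        assert back.reference_arm == "5DL"
        assert [r.marker_id for r in back.rows] == [r.marker_id for r in table.rows]
        for a, b in zip(table.rows, back.rows):
            assert a.hits == b.hits and a.band_count == b.band_count

    def test_breakpoints_bed_and_json(self, tmp_path):
        iv = BreakpointInterval(
            "5DL", "wheat_A", "ASA1", "PMEIL1", (1, 3),
            {"5AL"}, {"4AL"}, "5AL", "4AL", size_kb=15.0,
        )
        bed, sidecar = tmp_path / "b.bed", tmp_path / "b.json"
        io.write_breakpoints([iv], bed, sidecar)
        assert bed.read_text() == "5DL\t1\t3\twheat_A:ASA1|PMEIL1\n"
        (back,) = io.read_breakpoints(sidecar)
        assert back == iv

    def test_tracts_bed_and_density_tsv(self, tmp_path):
        profile = scan_tracts("AAAAAAA" + "CCG" * 40 + "TTTTTTTT")
        bed = tmp_path / "t.bed"
        io.write_tracts_bed(profile, "junction", bed)
        back = io.read_tracts_bed(bed, profile.sequence_length)
        assert back.tracts == profile.tracts
        dens = density_profile(profile, 100)
        tsv = tmp_path / "d.tsv"
        io.write_density_tsv(dens, 100, tsv)
        df = io.read_density_tsv(tsv)
        assert list(df["density"]) == list(dens)

    def test_junction_model_json_and_gff3(self, tmp_path):
        model = urartu_4al_junction()
        jpath = tmp_path / "model.json"
        io.write_junction_model(model, jpath)
        assert io.read_junction_model(jpath).segments == model.segments
        gpath = tmp_path / "model.gff3"
        io.write_junction_gff3(model, gpath)
        lines = gpath.read_text().splitlines()
        # GFF3 is 1-based inclusive: first segment is 1..706
        assert lines[1].split("\t")[3:5] == ["1", "706"]
        back = io.read_junction_gff3(gpath)
        assert back.segments == model.segments

    def test_fasta(self, tmp_path):
        records = {"a": "ACGTACGT", "b": "TTTTTTA"}
        path = tmp_path / "seqs.fasta"
        io.write_fasta(records, path)
        assert io.read_fasta(path) == records

    def test_newick_and_tip_states(self, tmp_path):
        import dendropy

        tree = dendropy.Tree.get(data=PAPER_TREE, schema="newick", preserve_underscores=True)
        npath = tmp_path / "tree.nwk"
        io.write_newick(tree, npath)
        back = io.read_newick(npath)
        assert {l.taxon.label for l in back.leaf_node_iter()} == set(PAPER_TIP_STATES)
        spath = tmp_path / "states.tsv"
        io.write_tip_states(PAPER_TIP_STATES, spath)
        assert io.read_tip_states(spath) == PAPER_TIP_STATES


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(seed=3, min_run=4, kb_per_band=2.0)
        path = tmp_path / "run.yaml"
        cfg.to_yaml(path)
        assert RunConfig.from_yaml(path) == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("min_run: 2\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            RunConfig.from_yaml(path)

    def test_defaults_document_the_constants(self):
        cfg = RunConfig()
        assert cfg.kb_per_band == 1.5
        assert cfg.min_tract_len == 6
        assert cfg.bin_size == 100

    def test_manifest_written(self, tmp_path):
        path = RunConfig(seed=12).write_manifest(tmp_path)
        manifest = json.loads(path.read_text())
        assert manifest["config"]["seed"] == 12
        assert "version" in manifest


class TestCli:
    def run(self, *args):
        return CliRunner().invoke(main, list(args))

    def test_paper_demo_matches_library(self, tmp_path):
        res = self.run("paper-demo", "--out", str(tmp_path))
        assert res.exit_code == 0, res.output
        on_disk = json.loads((tmp_path / "paper_demo.json").read_text())
        assert on_disk == run_paper_demo()
        assert on_disk["parsimony"]["min_origins"] == 2

    def test_paper_demo_byte_stable(self):
        out1, out2 = self.run("paper-demo").output, self.run("paper-demo").output
        assert out1 == out2

    def test_simulate_deterministic(self, tmp_path):
        dirs = [tmp_path / "r1", tmp_path / "r2"]
        for d in dirs:
            res = self.run("simulate", "--seed", "1", "--rate", "1.0", "--out", str(d))
            assert res.exit_code == 0, res.output
        files = sorted(p.name for p in dirs[0].iterdir())
        assert "genomes.tsv" in files and "events.json" in files
        for name in files:
            assert (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes()

    def test_scan_over_simulated_profile(self, tmp_path):
        sim = tmp_path / "sim"
        self.run("simulate", "--seed", "3", "--rate", "0.8", "--out", str(sim))
        profile = next(sim.glob("profile_*.tsv"))
        query = "B" if "_A_" in profile.name else "A"
        res = self.run(
            "scan", "--profile", str(profile), "--query", query,
            "--min-run", "2", "--out", str(tmp_path / "scan"),
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "scan" / "breakpoints.json").exists()

    def test_classify_on_fixture_genomes(self, tmp_path):
        gpath = tmp_path / "genomes.tsv"
        io.write_genomes_tsv(paper_genomes().values(), gpath)
        res = self.run(
            "classify", "--genomes", str(gpath), "--reference-taxon", "tauschii_D",
            "--query-taxon", "barley_H", "--out", str(tmp_path / "cls"),
        )
        assert res.exit_code == 0, res.output
        events = io.read_event_log(tmp_path / "cls" / "events.json")["barley_H"]
        assert {e.etype for e in events} >= {EventType.INVERSION}

    def test_parsimony_command(self, tmp_path):
        (tmp_path / "tree.nwk").write_text(PAPER_TREE)
        io.write_tip_states(PAPER_TIP_STATES, tmp_path / "states.tsv")
        res = self.run(
            "parsimony", "--tree", str(tmp_path / "tree.nwk"),
            "--states", str(tmp_path / "states.tsv"),
        )
        assert res.exit_code == 0, res.output
        assert json.loads(res.output) == {"fitch_changes": 2, "min_origins": 2}

    def test_junction_command(self, tmp_path):
        io.write_junction_model(urartu_4al_junction(), tmp_path / "model.json")
        res = self.run(
            "junction", "--model", str(tmp_path / "model.json"),
            "--exclude", "utr3", "--exclude-lineage-specific",
        )
        assert res.exit_code == 0, res.output
        assert json.loads(res.output)["length_bp"] == 1353

    def test_tracts_command_smoke(self, tmp_path):
        io.write_fasta({"toy": "AAAAAAAA" + "ACGT" * 30 + "TTTTTT"}, tmp_path / "toy.fasta")
        res = self.run(
            "tracts", "--fasta", str(tmp_path / "toy.fasta"), "--out", str(tmp_path / "tr")
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "tr" / "toy.tracts.bed").exists()
        assert (tmp_path / "tr" / "toy.density.tsv").exists()

    def test_bad_flag_usage_error(self):
        assert self.run("scan", "--bogus").exit_code == 2

    def test_missing_input_named_error(self, tmp_path):
        bad = tmp_path / "nope.tsv"
        bad.write_text("not\ta\tprofile\n")
        res = self.run("scan", "--profile", str(bad), "--query", "q", "--out", str(tmp_path / "o"))
        assert res.exit_code == 1
        assert "lacks columns" in res.output
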