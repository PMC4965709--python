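"""End-to-end workflow smoke tests, degradation contracts, and the CLI."""
import json

import numpy as np
import pytest
from click.testing import CliRunner

import blmdti as b
from blmdti.cli import main as cli_main
from blmdti.io import read_matrix_tsv


def _small_cfg(seed=9):
    return b.GeneratorConfig(
        n_compound_clusters=2, compounds_per_cluster=8,
        n_protein_families=2, proteins_per_family=4,
        p_in=0.9, p_out=0.0, decoration_rate=0.1,
        sequence_length_range=(60, 80), seed=seed,
    )


@pytest.fixture(scope="module")
def workdir(tmp_path_factory):
    root = tmp_path_factory.mktemp("flow")
    data = root / "data"
    b.generate_dataset(_small_cfg(), outdir=data)
    return root, data


def _run_cfg(root, data, **kw):
    return b.RunConfig(
        compounds=str(data / "compounds.smi"),
        proteins={"GPCR": str(data / "proteins.fasta")},
        interactions=str(data / "interactions.tsv"),
        outdir=str(root / "out"),
        cv_folds=4, seed=9, **kw,
    )


class TestTrainingWorkflow:
    def test_outputs_and_manifest(self, workdir):
        root, data = workdir
        manifest = b.run_training_workflow(_run_cfg(root, data))
        out = root / "out"
        for name in ("chem_similarity.tsv", "seq_similarity_GPCR.tsv",
                     "cv_report_GPCR.json", "cv_scores_GPCR.tsv", "manifest.json"):
            assert (out / name).exists(), name
        assert manifest["counts"]["GPCR"]["compounds"] == 16
        assert manifest["counts"]["GPCR"]["proteins"] == 8
        assert 0 <= manifest["pooled_metrics"]["GPCR"]["auc_pair"] <= 1
        assert manifest["cv_unit"] == "pair"
        # config hash in every output header
        chash = manifest["config_hash"]
        assert f"config_hash={chash}" in (out / "chem_similarity.tsv").read_text().splitlines()[0]
        report = json.loads((out / "cv_report_GPCR.json").read_text())
        assert report["cv_unit"] == "pair" and report["n_folds"] == 4

    def test_missing_inputs_listed_together(self, workdir, tmp_path):
        root, data = workdir
        cfg = b.RunConfig(compounds=str(tmp_path / "no.smi"),
                          proteins={"GPCR": str(tmp_path / "no.fasta")},
                          interactions=str(data / "interactions.tsv"),
                          outdir=str(tmp_path / "out"))
        with pytest.raises(b.ValidationError) as exc:
            b.run_training_workflow(cfg)
        assert "no.smi" in str(exc.value) and "no.fasta" in str(exc.value)

    def test_class_with_single_protein_skipped_others_complete(self, workdir, tmp_path):
        root, data = workdir
        lone = tmp_path / "lone.fasta"
        lone.write_text(">solo\nMKVLWAALLVTFLAGCQA\n")
        edges = tmp_path / "edges.tsv"
        base = (data / "interactions.tsv").read_text()
        edges.write_text(base + "cmpd0_000\tsolo\tenzyme\n")
        cfg = b.RunConfig(
            compounds=str(data / "compounds.smi"),
            proteins={"GPCR": str(data / "proteins.fasta"), "enzyme": str(lone)},
            interactions=str(edges), outdir=str(tmp_path / "out"), cv_folds=4, seed=9)
        manifest = b.run_training_workflow(cfg)
        assert "GPCR" in manifest["pooled_metrics"]
        assert "enzyme" not in manifest["pooled_metrics"]

    def test_different_configs_different_hashes(self, workdir):
        root, data = workdir
        h1 = _run_cfg(root, data).config_hash()
        h2 = _run_cfg(root, data, fingerprint_width=2048).config_hash()
        assert h1 != h2


class TestScreeningWorkflow:
    def test_self_screen_recovers_training_positives(self, workdir, tmp_path):
        """Screening the training library against its own targets: every
        known edge of a trainable target reappears with a positive score."""
        root, data = workdir
        cfg = _run_cfg(root, data, query_compounds=str(data / "compounds.smi"))
        cfg.outdir = str(tmp_path / "screen")
        b.run_screening_workflow(cfg)
        hits = (tmp_path / "screen" / "hits_GPCR.tsv").read_text().splitlines()
        predicted = {tuple(l.split("\t")[:2]) for l in hits[2:]}
        inter = b.read_interactions(data / "interactions.tsv")["GPCR"]
        assert inter.edges <= predicted
        assert (tmp_path / "screen" / "rof_profile.tsv").exists()
        rof = (tmp_path / "screen" / "rof_descriptors.tsv").read_text().splitlines()
        assert rof[1].startswith("id\t")

    def test_empty_query_library_is_an_error(self, workdir, tmp_path):
        root, data = workdir
        empty = tmp_path / "empty.smi"
        empty.write_text("# nothing\n")
        cfg = _run_cfg(root, data, query_compounds=str(empty))
        cfg.outdir = str(tmp_path / "out")
        with pytest.raises(b.ValidationError, match="empty"):
            b.run_screening_workflow(cfg)

    def test_unparseable_query_in_strict_mode_errors(self, workdir, tmp_path):
        root, data = workdir
        bad = tmp_path / "bad.smi"
        bad.write_text("q1\tC(\n")
        cfg = _run_cfg(root, data, query_compounds=str(bad), strict_query=True)
        cfg.outdir = str(tmp_path / "out")
        with pytest.raises(b.ValidationError):
            b.run_screening_workflow(cfg)

    def test_infinite_threshold_empty_hits(self, workdir, tmp_path):
        root, data = workdir
        cfg = _run_cfg(root, data, query_compounds=str(data / "compounds.smi"),
                       screening_threshold=float("inf"))
        cfg.outdir = str(tmp_path / "thresh")
        manifest = b.run_screening_workflow(cfg)
        assert manifest["counts"]["GPCR"]["predicted_edges"] == 0
        hits = (tmp_path / "thresh" / "hits_GPCR.tsv").read_text().splitlines()
        assert len(hits) == 2  # comment + header only


class TestCli:
    def test_simulate_chemsim_seqsim_rof(self, tmp_path):
        runner = CliRunner()
        cfg_yaml = tmp_path / "sim.yaml"
        cfg_yaml.write_text(
            "n_compound_clusters: 2\ncompounds_per_cluster: 4\n"
            "n_protein_families: 2\nproteins_per_family: 3\n"
            "sequence_length_range: [40, 50]\n")
        out = tmp_path / "fix"
        r = runner.invoke(cli_main, ["simulate", "--config", str(cfg_yaml),
                                     "--seed", "3", "--outdir", str(out)])
        assert r.exit_code == 0, r.output
        assert (out / "compounds.smi").exists() and (out / "labels.tsv").exists()

        r = runner.invoke(cli_main, ["chemsim", "--smiles", str(out / "compounds.smi"),
                                     "--out", str(tmp_path / "chem.tsv")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["seqsim", "--fasta", str(out / "proteins.fasta"),
                                     "--out", str(tmp_path / "seq.tsv")])
        assert r.exit_code == 0, r.output
        rows, cols, vals = read_matrix_tsv(tmp_path / "seq.tsv")
        assert rows == cols and np.allclose(np.diag(vals), 1.0)

        r = runner.invoke(cli_main, ["rof", "--smiles", str(out / "compounds.smi"),
                                     "--out", str(tmp_path / "rof.tsv")])
        assert r.exit_code == 0, r.output

    def test_error_is_machine_readable_json(self, tmp_path):
        runner = CliRunner(mix_stderr=False) if "mix_stderr" in CliRunner.__init__.__code__.co_varnames else CliRunner()
        lib = tmp_path / "dup.smi"
        lib.write_text("c1\tCCO\nc1\tCC\n")
        r = runner.invoke(cli_main, ["chemsim", "--smiles", str(lib),
                                     "--out", str(tmp_path / "o.tsv")])
        assert r.exit_code == 1
        err_text = getattr(r, "stderr", None) or r.output
        payload = json.loads(err_text.strip().splitlines()[-1])
        assert payload["error"] == "ValidationError"
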