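import numpy as np
import pytest

from seqdemux import (GenomicSite, KmerSpace, LabeledDataset, PWM, WeightSet,
                      load_fasta, load_sites)
from seqdemux.dataio import (read_meme, read_site_table, read_weight_table,
                             saturate, write_fasta, write_hills_bed, write_meme,
                             write_outputs, write_weight_tables)
from seqdemux.hills import Hill
from seqdemux.model import LabelStructure
from seqdemux.motifs import MotifScoreTable
from seqdemux.simulate import BUNDLED_PWMS


@pytest.fixture(scope="module")
def toy_genome(tmp_path_factory):
    """Two-chromosome FASTA with a deterministic sequence."""
    rng = np.random.default_rng(77)
    chroms = {
        "chr1": "".join(rng.choice(list("ACGT"), size=5000)),
        "chr2": "".join(rng.choice(list("ACGT"), size=3000)),
    }
    path = tmp_path_factory.mktemp("genome") / "toy.fa"
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n{seq}\n")
    return path, chroms


class TestSiteTable:
    def test_interval_rows_use_midpoint(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("chr1\t100\t200\tA;B\nchr2\t50\tX\n")
        sites = read_site_table(p)
        assert sites[0].position == 150 and sites[0].labels == {"A", "B"}
        assert sites[1].position == 50 and sites[1].labels == {"X"}

    def test_empty_label_field_reports_line_number(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("chr1\t100\t200\tA\nchr1\t300\t400\t;\n")
        with pytest.raises(ValueError, match="line 2"):
            read_site_table(p)

    def test_site_invariants(self):
        with pytest.raises(ValueError):
            GenomicSite("chr1", -5, {"A"})
        with pytest.raises(ValueError):
            GenomicSite("chr1", 5, set())


class TestLoadSites:
    def test_window_extraction_matches_substring_oracle(self, toy_genome, tmp_path):
        path, chroms = toy_genome
        rng = np.random.default_rng(5)
        rows, expected = [], []
        for _ in range(100):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            pos = int(rng.integers(100, len(chroms[chrom]) - 100))
            rows.append(f"{chrom}\t{pos}\tA")
            expected.append(chroms[chrom][pos - 75:pos + 75])
        sites_file = tmp_path / "s.tsv"
        sites_file.write_text("\n".join(rows) + "\n")
        ds = load_sites(sites_file, path, window=150)
        assert ds.sequences == expected

    def test_out_of_bounds_sites_dropped(self, toy_genome, tmp_path):
        path, _ = toy_genome
        f = tmp_path / "s.tsv"
        f.write_text("chr1\t10\tA\nchr1\t1000\tA\nchr1\t2000\tB\n")
        ds = load_sites(f, path, window=150)
        assert ds.M == 2

    def test_missing_chromosome_named_in_error(self, toy_genome, tmp_path):
        path, _ = toy_genome
        f = tmp_path / "s.tsv"
        f.write_text("chrMT\t500\tA\n")
        with pytest.raises(KeyError, match="chrMT"):
            load_sites(f, path)

    def test_odd_window_rejected(self, toy_genome, tmp_path):
        path, _ = toy_genome
        f = tmp_path / "s.tsv"
        f.write_text("chr1\t500\tA\n")
        with pytest.raises(ValueError):
            load_sites(f, path, window=151)


class TestDataset:
    def test_subclass_and_weight_derivation(self):
        labels = [{"A"}] * 200 + [{"A", "X"}] * 100 + [{"X"}] * 100
        ds = LabeledDataset(sequences=["ACGT" * 10] * 400, label_sets=labels)
        assert len(ds.structure.subclasses) == 3
        assert ds.b[:200].max() == 1.0
        assert ds.b[200] == 2.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            LabeledDataset(sequences=["ACGT", "ACGTA"],
                           label_sets=[{"A"}, {"A"}])


class TestFastaRoundTrip:
    def test_labels_in_headers(self, tmp_path):
        f = tmp_path / "seqs.fa"
        write_fasta(["ACGTACGT", "TTTTAAAA"], [{"A", "X"}, {"B"}], f)
        ds = load_fasta(f)
        assert ds.label_sets == [{"A", "X"}, {"B"}]

    def test_sidecar_label_table(self, tmp_path):
        f = tmp_path / "seqs.fa"
        f.write_text(">s1\nACGTACGT\n>s2\nTTTTAAAA\n")
        t = tmp_path / "labels.tsv"
        t.write_text("s1\tA;X\ns2\tB\n")
        ds = load_fasta(f, label_table=t)
        assert ds.label_sets == [{"A", "X"}, {"B"}]

    def test_missing_sidecar_entry_rejected(self, tmp_path):
        f = tmp_path / "seqs.fa"
        f.write_text(">s1\nACGT\n")
        t = tmp_path / "labels.tsv"
        t.write_text("other\tA\n")
        with pytest.raises(KeyError):
            load_fasta(f, label_table=t)


class TestWeightTables:
    def test_round_trip_preserves_values(self, tmp_path, rng):
        space = KmerSpace()
        labels = [{"A"}, {"A", "X"}, {"X"}]
        s = LabelStructure.from_label_sets(labels)
        W = WeightSet.zeros(s, space.K_dim)
        W.W_sub = rng.normal(size=W.W_sub.shape)
        W.W_lab = rng.normal(size=W.W_lab.shape)
        write_weight_tables(W, space, tmp_path)
        lab = read_weight_table(tmp_path / "label_weights.tsv")
        assert lab.shape == (648, 2)
        assert np.abs(lab.values - W.W_lab.T).max() < 1e-9


class TestMeme:
    def test_round_trip(self, tmp_path):
        motifs = [PWM(BUNDLED_PWMS["ebox"], name="ebox"),
                  PWM(BUNDLED_PWMS["ap1"], name="ap1")]
        f = tmp_path / "m.meme"
        write_meme(motifs, f)
        back = read_meme(f)
        assert [m.name for m in back] == ["ebox", "ap1"]
        assert np.abs(back[0].matrix - motifs[0].matrix).max() < 1e-6

    def test_empty_motif_set_writes_valid_header(self, tmp_path):
        f = tmp_path / "empty.meme"
        write_meme([], f)
        text = f.read_text()
        assert text.startswith("MEME version")
        assert read_meme(f) == []


class TestOutputs:
    def test_saturation_clamps_scores(self):
        assert saturate(np.array([0.55, -0.7, 0.1])).tolist() == [0.4, -0.4, 0.1]

    def test_hills_bed_sequence_relative(self, tmp_path):
        hills = [Hill(seq_id=2, start=10, end=25, score=0.5,
                      source_model="A", dna="ACGTACGTACGTACG")]
        f = tmp_path / "hills.bed"
        write_hills_bed(hills, f)
        assert f.read_text() == "seq2\t10\t25\tA\t0.5000\n"

    def test_write_outputs_bundle(self, tmp_path, rng):
        space = KmerSpace()
        labels = [{"A"}, {"A", "X"}, {"X"}]
        s = LabelStructure.from_label_sets(labels)
        W = WeightSet.zeros(s, space.K_dim)
        motifs = [PWM(BUNDLED_PWMS["ebox"], name="m1")]
        table = MotifScoreTable(motifs=motifs, model_names=["A", "X"],
                                scores=np.array([[0.3, -0.1]]))
        out = write_outputs(W, space, table, tmp_path / "run",
                            config={"lam": 10.0})
        for name in ("label_weights.tsv", "subclass_weights.tsv",
                     "motifs.meme", "motif_scores.tsv", "motif_scores.png",
                     "run_log.yaml"):
            assert (out / name).exists()
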