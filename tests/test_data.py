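"""Data I/O, preprocessing rules, splitting and the fixture generator."""

import numpy as np
import pandas as pd
import pytest

from mgfdta.data import (AffinityDataset, generate_fixture, load_table,
                         make_repeats, pkd_from_kd_nm, planted_label,
                         preprocess_bindingdb, save_table, split)
from mgfdta.errors import (EmptyInputError, InvalidParameterError, SchemaError)
from mgfdta.kmer import extract_kmers


def toy_table(tmp_path, rows, name="toy.csv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


TOY_ROWS = [
    {"drug_id": "d1", "smiles": "CCO", "protein_id": "p1",
     "sequence": "MATSK", "label": 5.0},
    {"drug_id": "d1", "smiles": "CCO", "protein_id": "p2",
     "sequence": "MATTE", "label": 6.1},
    {"drug_id": "d2", "smiles": "CCN", "protein_id": "p1",
     "sequence": "MATSK", "label": 7.2},
]


class TestLoadTable:
    def test_three_row_csv(self, tmp_path):
        ds = load_table(toy_table(tmp_path, TOY_ROWS))
        assert len(ds) == 3
        assert ds.pairs.loc[1, "label"] == 6.1

    def test_non_numeric_label_rejected_with_line_number(self, tmp_path):
        rows = TOY_ROWS + [{"drug_id": "d3", "smiles": "CC", "protein_id": "p3",
                            "sequence": "CATSE", "label": "strong"}]
        ds = load_table(toy_table(tmp_path, rows))
        assert len(ds) == 3
        assert ds.provenance["rejected"] == [
            {"line": 5, "reason": "non-numeric label", "value": "strong"}]

    def test_missing_column_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame([{"drug_id": "d", "smiles": "C"}]).to_csv(path, index=False)
        with pytest.raises(SchemaError):
            load_table(path)

    def test_roundtrip_write_read(self, tmp_path):
        ds = load_table(toy_table(tmp_path, TOY_ROWS))
        out = tmp_path / "out.tsv"
        save_table(ds, out)
        again = load_table(out)
        pd.testing.assert_frame_equal(
            again.pairs[list(ds.pairs.columns[:-1])],
            ds.pairs[list(ds.pairs.columns[:-1])])

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(InvalidParameterError):
            AffinityDataset(pairs=pd.DataFrame([TOY_ROWS[0], TOY_ROWS[0]]))


class TestBindingDBPreprocessing:
    RAW = pd.DataFrame([
        # survives: affinity 1 nM -> label 9
        {"drug_id": "d1", "smiles": "CCO", "protein_id": "P11111",
         "sequence": "MATSK", "chains": 1, "affinity": "1"},
        # survives after duplicate resolution: 1000 nM -> label 6
        {"drug_id": "d2", "smiles": "CCN", "protein_id": "P22222",
         "sequence": "MATTE", "chains": 1, "affinity": "1000"},
        # duplicate of (d2, P22222) with lower affinity: dropped
        {"drug_id": "d2", "smiles": "CCN", "protein_id": "P22222",
         "sequence": "MATTE", "chains": 1, "affinity": "10"},
        # multi-chain: dropped
        {"drug_id": "d3", "smiles": "CC", "protein_id": "P33333",
         "sequence": "CATSE", "chains": 2, "affinity": "5"},
        # no UniProt id: dropped
        {"drug_id": "d4", "smiles": "CCC", "protein_id": "",
         "sequence": "CATSE", "chains": 1, "affinity": "5"},
        # no affinity label: dropped
        {"drug_id": "d5", "smiles": "CCCC", "protein_id": "P55555",
         "sequence": "CATSE", "chains": 1, "affinity": None},
    ])

    def test_six_record_fixture_yields_two_pairs(self):
        ds = preprocess_bindingdb(self.RAW)
        assert len(ds) == 2
        by_drug = ds.pairs.set_index("drug_id")["label"]
        assert by_drug["d1"] == pytest.approx(9.0)   # 9 - log10(1)
        assert by_drug["d2"] == pytest.approx(6.0)   # 9 - log10(1000)
        reasons = [r["reason"] for r in ds.provenance["rejected"]]
        assert sorted(reasons) == sorted([
            "multi-chain protein", "missing UniProt id",
            "missing affinity label", "duplicate pair (lower affinity)"])

    def test_duplicate_keeps_higher_raw_affinity(self):
        ds = preprocess_bindingdb(self.RAW)
        # 1000 nM (higher raw value) kept over 10 nM
        assert ds.pairs.set_index("drug_id").loc["d2", "label"] == pytest.approx(6.0)

    def test_nonpositive_affinity_rejected_with_reason(self):
        raw = self.RAW.iloc[:1].assign(affinity="-2")
        ds = preprocess_bindingdb(raw)
        assert len(ds) == 0
        assert ds.provenance["rejected"][0]["reason"] == "non-positive affinity"

    def test_idempotence(self):
        ds = preprocess_bindingdb(self.RAW)
        raw_again = ds.pairs.assign(chains=1,
                                    affinity=10 ** (9 - ds.pairs["label"]))
        again = preprocess_bindingdb(raw_again.drop(columns=["label", "split"]))
        np.testing.assert_allclose(sorted(again.pairs["label"]),
                                   sorted(ds.pairs["label"]))

    def test_pkd_transform_convention(self):
        assert pkd_from_kd_nm(1.0) == pytest.approx(9.0)
        assert pkd_from_kd_nm(1e9) == pytest.approx(0.0)
        with pytest.raises(InvalidParameterError):
            pkd_from_kd_nm(0.0)


class TestSplits:
    def test_eighty_ten_ten_counts(self, fixture_dataset):
        counts = fixture_dataset.pairs["split"].value_counts()
        assert counts["train"] == 160 and counts["valid"] == 20 \
            and counts["test"] == 20

    def test_same_seed_reproduces_assignment(self):
        ds = generate_fixture(seed=3)
        a = split(ds, seed=11).pairs["split"]
        b = split(ds, seed=11).pairs["split"]
        pd.testing.assert_series_equal(a, b)
        assert not a.equals(split(ds, seed=12).pairs["split"])

    def test_assignments_disjoint_and_exhaustive(self, fixture_dataset):
        assert fixture_dataset.pairs["split"].notna().all()
        assert set(fixture_dataset.pairs["split"]) == {"train", "valid", "test"}

    def test_bad_ratios_rejected(self):
        with pytest.raises(InvalidParameterError):
            split(generate_fixture(seed=0), ratios=(0.8, 0.1, 0.2))

    def test_repeated_cv_schedule_bookkeeping(self):
        ds = generate_fixture(n_drugs=10, n_proteins=10, seed=5)  # 100 pairs
        schedule = make_repeats(ds, repeats=5, folds=5, seed=0)
        assert len(schedule) == 25
        for r in range(5):
            entries = [e for e in schedule if e["repeat"] == r]
            test = set(entries[0]["test"])
            pool = set(range(100)) - test
            fold_sets = [set(e["valid"]) for e in entries]
            # folds are disjoint and partition the pool
            assert set().union(*fold_sets) == pool
            assert sum(len(f) for f in fold_sets) == len(pool)
            for e in entries:
                assert set(e["train"]) | set(e["valid"]) == pool
                assert not set(e["train"]) & set(e["valid"])
                assert not test & (set(e["train"]) | set(e["valid"]))

    def test_too_small_for_folds(self):
        with pytest.raises(EmptyInputError):
            make_repeats(generate_fixture(n_drugs=1, n_proteins=3, seed=0),
                         folds=5)


class TestFixtureGenerator:
    def test_seed_reproducibility(self):
        a = generate_fixture(seed=9)
        b = generate_fixture(seed=9)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)

    def test_sizes_and_density(self):
        assert len(generate_fixture(seed=0)) == 200
        assert len(generate_fixture(n_drugs=4, n_proteins=5, density=0.5,
                                    seed=0)) == 10

    def test_noise_free_labels_recompute_from_planted_rule(self):
        ds = generate_fixture(seed=2, noise_sd=0.0)
        motifs = ds.provenance["motifs"]
        for row in ds.pairs.itertuples():
            assert row.label == pytest.approx(
                planted_label(motifs[row.drug_id], row.sequence), abs=1e-12)

    def test_planted_rule_beats_mean_baseline(self):
        ds = generate_fixture(seed=4)
        motifs = ds.provenance["motifs"]
        y = ds.pairs["label"].to_numpy()
        rule = np.array([planted_label(motifs[r.drug_id], r.sequence)
                         for r in ds.pairs.itertuples()])
        assert np.mean((y - rule) ** 2) < np.var(y)

    def test_smiles_are_rdkit_valid(self):
        from rdkit import Chem
        ds = generate_fixture(seed=6)
        for s in ds.pairs["smiles"].unique():
            assert Chem.MolFromSmiles(s) is not None, s

    def test_protein_lengths_in_range(self):
        ds = generate_fixture(seed=8)
        lengths = ds.pairs["sequence"].str.len()
        assert lengths.between(50, 300).all()

    def test_overlap_signal_present(self):
        # labels correlate with the planted 3-mer overlap fraction
        ds = generate_fixture(seed=1)
        motifs = ds.provenance["motifs"]
        overlaps = []
        for r in ds.pairs.itertuples():
            mk = set(extract_kmers(motifs[r.drug_id], 3))
            sk = extract_kmers(r.sequence, 3)
            overlaps.append(sum(1 for m in sk if m in mk) / len(sk))
        assert np.corrcoef(overlaps, ds.pairs["label"])[0, 1] > 0.9
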