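"""Counting semantics, coverage, and dataset statistics."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from biosynkey.fingerprint import (
    atom_coverage,
    batch_fingerprint,
    binarise,
    cooccurrence_pmi,
    count_matches,
    fingerprint_molecule,
    occurrence_stats,
)
from biosynkey.structio import record_from_smiles


class TestCountMatches:
    def test_benzene_six_ring_counts_once_despite_twelve_walks(self, registry):
        benzene = record_from_smiles("c1ccccc1")
        assert count_matches(benzene, registry["ring6_carbocycle"]) == 1

    def test_ethanol_has_one_hydroxyl(self, registry):
        assert count_matches(record_from_smiles("CCO"), registry["hydroxyl"]) == 1

    def test_glucopyranose_has_five_hydroxyls(self, registry):
        glucose = record_from_smiles("OCC1OC(O)C(O)C(O)C1O")
        assert count_matches(glucose, registry["hydroxyl"]) == 5

    def test_overlapping_placements_of_one_key_all_count(self, registry):
        # hexane-1,6-diol: two hydroxyls, four acetyl (C-C-O) placements
        diol = record_from_smiles("OCCCCCCO")
        assert count_matches(diol, registry["hydroxyl"]) == 2


class TestFingerprintMolecule:
    def test_methane_is_all_zero(self, registry):
        fp = fingerprint_molecule(record_from_smiles("C"), registry)
        assert fp.counts.sum() == 0
        assert len(fp) == 39

    def test_fluorobenzene_hits_fluorine_and_six_ring(self, registry):
        fp = fingerprint_molecule(record_from_smiles("Fc1ccccc1"), registry)
        by_name = dict(zip(registry.names, fp.counts))
        assert by_name["fluorine"] == 1
        assert by_name["ring6_carbocycle"] == 1

    def test_disconnected_dimer_doubles_every_count(self, registry):
        single = fingerprint_molecule(record_from_smiles("OCC1OC(O)C(O)C(O)C1O"), registry)
        dimer = fingerprint_molecule(
            record_from_smiles("OCC1OC(O)C(O)C(O)C1O.OCC1OC(O)C(O)C(O)C1O"), registry
        )
        assert (dimer.counts == 2 * single.counts).all()

    def test_additivity_over_components(self, registry, small_records):
        for a, b in [(small_records[1], small_records[8]), (small_records[3], small_records[19])]:
            combined = record_from_smiles(f"{a.smiles}.{b.smiles}")
            fa = fingerprint_molecule(a, registry).counts
            fb = fingerprint_molecule(b, registry).counts
            fc = fingerprint_molecule(combined, registry).counts
            assert (fc == fa + fb).all()

    def test_binarise_indicates_presence(self, registry):
        fp = fingerprint_molecule(record_from_smiles("CCO"), registry)
        binary = binarise(fp)
        assert set(np.unique(binary)) <= {0, 1}
        assert ((fp.counts > 0) == (binary == 1)).all()


class TestOracleEquivalence:
    def test_production_matcher_agrees_with_naive_enumerator(
        self, registry, small_records, oracle
    ):
        """Distinct-atom-set counts equal brute-force monomorphism counts."""
        for record in small_records:
            assert record.heavy_atom_count <= 12
            for key in registry:
                expected = oracle(record.mol, key.smarts_relaxed)
                assert count_matches(record, key) == expected, (
                    f"{record.id} x {key.name}"
                )

    def test_oracle_agreement_on_assembled_fixtures(self, registry, oracle):
        from biosynkey.fixtures import BlockRecipe, assemble

        for recipe in [("isoprene_c5", "isoprene_c5"), ("acetyl_c2",) * 3,
                       ("benzyl_c6c1", "hydroxyl")]:
            record, _ = assemble(BlockRecipe(recipe))
            if record.heavy_atom_count > 12:
                continue
            for key in registry:
                assert count_matches(record, key) == oracle(
                    record.mol, key.smarts_relaxed
                ), f"{record.id} x {key.name}"


class TestAtomCoverage:
    def test_fully_covered_molecule(self, registry):
        glucose = record_from_smiles("OCC1OC(O)C(O)C(O)C1O")
        assert atom_coverage(glucose, registry).coverage == 1.0

    def test_methane_uncovered(self, registry):
        assert atom_coverage(record_from_smiles("C"), registry).coverage == 0.0

    def test_ethanol_with_hydroxyl_only_registry_covers_one_third(self, registry):
        reduced = registry.subset(["hydroxyl"])
        result = atom_coverage(record_from_smiles("CCO"), reduced)
        assert result.covered_heavy_atoms == 1
        assert result.total_heavy_atoms == 3
        assert result.coverage == pytest.approx(1 / 3)

    def test_adding_a_key_never_decreases_coverage(self, registry, small_records):
        reduced = registry.subset(registry.names[:10])
        for record in small_records:
            assert (
                atom_coverage(record, registry).coverage
                >= atom_coverage(record, reduced).coverage
            )

    def test_removing_a_key_never_increases_counts(self, registry, small_records):
        reduced = registry.subset([n for n in registry.names if n != "hydroxyl"])
        for record in small_records[:8]:
            full = dict(zip(registry.names, fingerprint_molecule(record, registry).counts))
            small = dict(zip(reduced.names, fingerprint_molecule(record, reduced).counts))
            for name, count in small.items():
                assert count == full[name]


class TestBatchAndStats:
    def test_batch_preserves_order_and_is_deterministic(self, registry, small_records):
        table = batch_fingerprint(small_records, registry)
        assert list(table.index) == [r.id for r in small_records]
        again = batch_fingerprint(small_records, registry)
        pd.testing.assert_frame_equal(table, again)

    def test_methane_row_is_zero_with_zero_coverage(self, registry, small_records):
        table = batch_fingerprint(small_records, registry)
        row = table.loc["methane"]
        assert row[registry.names].sum() == 0
        assert row["coverage"] == 0.0

    def test_occurrence_stats_on_single_molecule_equal_its_counts(self, registry):
        rec = record_from_smiles("OCC1OC(O)C(O)C(O)C1O", "glc")
        table = batch_fingerprint([rec], registry, with_coverage=False)
        stats = occurrence_stats(table)
        assert (stats["mean"] == table.iloc[0]).all()
        assert (stats["max"] == table.iloc[0]).all()

    def test_fluorine_free_set_has_zero_fluorine_occurrence(self, registry, small_records):
        no_f = [r for r in small_records if r.id != "fluorobenzene"]
        stats = occurrence_stats(batch_fingerprint(no_f, registry, with_coverage=False))
        assert stats.loc["fluorine", "mean"] == 0
        assert stats.loc["fluorine", "max"] == 0

    def test_mean_of_zero_and_two_is_one(self, registry):
        table = pd.DataFrame({"hydroxyl": [0, 2]})
        assert occurrence_stats(table).loc["hydroxyl", "mean"] == 1.0


class TestCooccurrencePMI:
    @staticmethod
    def _table(columns):
        return pd.DataFrame(columns)

    def test_independent_keys_have_zero_pmi(self):
        # p(a)=p(b)=0.5, p(a and b)=0.25 over four molecules
        table = self._table({"a": [1, 1, 0, 0], "b": [1, 0, 1, 0]})
        pmi = cooccurrence_pmi(table)
        assert pmi.loc["a", "b"] == pytest.approx(0.0)

    def test_perfect_cooccurrence_gives_plus_one(self):
        table = self._table({"a": [3, 1, 0, 0], "b": [1, 2, 0, 0]})
        pmi = cooccurrence_pmi(table)
        assert pmi.loc["a", "b"] == pytest.approx(1.0)

    def test_mutually_exclusive_keys_are_minus_infinity(self):
        table = self._table({"a": [1, 0], "b": [0, 1]})
        assert cooccurrence_pmi(table).loc["a", "b"] == -np.inf

    def test_zero_marginal_is_undefined(self):
        table = self._table({"a": [1, 1], "b": [0, 0]})
        assert np.isnan(cooccurrence_pmi(table).loc["a", "b"])

    def test_diagonal_is_negative_log_marginal(self):
        table = self._table({"a": [1, 0, 0, 0]})
        table["b"] = [1, 1, 0, 0]
        pmi = cooccurrence_pmi(table)
        assert pmi.loc["a", "a"] == pytest.approx(2.0)  # -log2(1/4)
        assert pmi.loc["b", "b"] == pytest.approx(1.0)

    def test_matrix_is_symmetric(self, registry, small_records):
        from biosynkey.fingerprint import batch_fingerprint

        table = batch_fingerprint(small_records, registry, with_coverage=False)
        pmi = cooccurrence_pmi(table).to_numpy()
        finite = np.isfinite(pmi)
        assert (finite == finite.T).all()
        assert np.allclose(pmi[finite & finite.T], pmi.T[finite & finite.T])
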