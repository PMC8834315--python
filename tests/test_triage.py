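import dataclasses

import numpy as np
import pytest

from npcquant.errors import DomainError, SmilesParseError, ValidationError, VinaParseError
from npcquant.triage import (
    CHOLESTEROL_REFERENCE_ENERGY,
    CompoundRecord,
    DockingModeList,
    HitCriterion,
    heavy_atom_count,
    ligand_efficiency,
    parse_vina_result,
    rank_compounds,
    select_hits,
    serialize_modes,
    verify_efficiency_table,
)

CHOLESTEROL_SMILES = "CC(C)CCC[C@@H](C)[C@H]1CC[C@H]2[C@@H]3CC=C4C[C@@H](O)CC[C@]4(C)[C@H]3CC[C@]12C"
ABIRATERONE_SMILES = "C[C@]12CC[C@H]3[C@@H](CC=C4C[C@@H](O)CC[C@]34C)[C@@H]1CC=C2c1cccnc1"


class TestHeavyAtomCount:
    def test_ethanol(self):
        assert heavy_atom_count("CCO") == 3

    def test_cholesterol_c27h46o(self):
        # 27 C + 1 O non-hydrogen atoms in the molecular formula
        assert heavy_atom_count(CHOLESTEROL_SMILES) == 28

    def test_abiraterone_c24h31no(self):
        # 24 C + 1 N + 1 O
        assert heavy_atom_count(ABIRATERONE_SMILES) == 26

    @pytest.mark.parametrize("bad", ["not a molecule((", "", "C(C"])
    def test_unparseable_smiles(self, bad):
        with pytest.raises(SmilesParseError):
            heavy_atom_count(bad)


class TestLigandEfficiency:
    def test_cholesterol_row(self):
        assert round(ligand_efficiency(-11.3, 28), 3) == -0.404

    def test_zero_energy(self):
        assert ligand_efficiency(0.0, 17) == 0.0

    def test_dydrogesterone_row(self):
        assert round(ligand_efficiency(-12.6, 23), 3) == -0.548

    def test_bad_heavy_count(self):
        with pytest.raises(DomainError):
            ligand_efficiency(-10.0, 0)

    def test_linearity(self, rng):
        for _ in range(50):
            e = rng.uniform(-15, -1)
            n = int(rng.integers(1, 60))
            c = rng.uniform(-3, 3)
            assert ligand_efficiency(c * e, n) == pytest.approx(
                c * ligand_efficiency(e, n)
            )

    def test_sign_matches_energy(self):
        assert ligand_efficiency(-5.0, 10) < 0
        assert ligand_efficiency(5.0, 10) > 0


class TestVerifyEfficiencyTable:
    def test_all_reference_rows_pass(self, reference_records):
        assert verify_efficiency_table(reference_records) == [True] * 12

    def test_mistyped_efficiency_fails(self, reference_records):
        rec = dataclasses.replace(
            reference_records[0],
            binding_efficiency=reference_records[0].binding_efficiency + 0.01,
        )
        assert verify_efficiency_table([rec]) == [False]

    def test_quinestrol_two_decimal_precision(self):
        # -11.6/27 = -0.4296..., within 0.005 of the printed -0.43
        rec = CompoundRecord(
            compound_id="DB04575",
            name="Quinestrol",
            binding_energy=-11.6,
            heavy_atom_count=27,
            binding_efficiency=-0.43,
            efficiency_decimals=2,
        )
        assert verify_efficiency_table([rec]) == [True]

    def test_missing_field_lists_row_ids(self):
        rec = CompoundRecord(compound_id="X1", name="x", binding_energy=-10.0,
                             heavy_atom_count=20)
        with pytest.raises(ValidationError, match="X1"):
            verify_efficiency_table([rec])


class TestSelectHits:
    def test_all_ten_candidates_retained(self, candidate_records):
        hits = select_hits(candidate_records, HitCriterion())
        assert len(hits) == 10

    def test_boundary_tie_retained(self):
        rec = CompoundRecord(compound_id="DB01420", name="Testosterone propionate",
                             binding_energy=-11.3, heavy_atom_count=25)
        assert select_hits([rec], HitCriterion(reference_energy=-11.3)) == [rec]

    def test_weaker_binder_excluded(self):
        rec = CompoundRecord(compound_id="X", name="x", binding_energy=-10.0,
                             heavy_atom_count=20)
        assert select_hits([rec], HitCriterion(reference_energy=-11.3)) == []

    def test_empty_input_gives_empty_list(self):
        assert select_hits([], HitCriterion()) == []

    def test_reference_rows_never_hits(self, reference_records):
        hits = select_hits(reference_records, HitCriterion())
        assert all(not h.is_reference for h in hits)

    def test_idempotent_and_subset(self, candidate_records):
        crit = HitCriterion()
        once = select_hits(candidate_records, crit)
        assert select_hits(once, crit) == once
        assert set(h.compound_id for h in once) <= set(
            r.compound_id for r in candidate_records
        )

    def test_monotone_in_reference_energy(self, candidate_records, rng):
        refs = sorted(rng.uniform(-13.5, -10.0, size=10))
        previous: set = set()
        for ref in refs:  # loosening (less negative) never removes a hit
            ids = {h.compound_id for h in select_hits(candidate_records,
                                                      HitCriterion(ref))}
            assert previous <= ids
            previous = ids

    def test_noninclusive_criterion_rejected(self):
        with pytest.raises(ValidationError):
            HitCriterion(inclusive=False)


class TestRankCompounds:
    def test_top_two_ranks(self, candidate_records):
        table = rank_compounds(candidate_records)
        assert list(table["name"][:2]) == ["Dydrogesterone", "Lumacaftor"]
        assert list(table["binding_energy"][:2]) == [-12.6, -12.1]

    def test_single_record(self):
        rec = CompoundRecord(compound_id="A", name="a", binding_energy=-9.0,
                             heavy_atom_count=10)
        table = rank_compounds([rec])
        assert list(table["rank"]) == [1]

    def test_equal_energy_ordered_by_efficiency(self):
        # oracle: enumerate both orderings against the stated tie rule —
        # smaller (more negative) efficiency must come first
        a = CompoundRecord(compound_id="A", name="a", binding_energy=-10.0,
                           heavy_atom_count=20)  # eff -0.50
        b = CompoundRecord(compound_id="B", name="b", binding_energy=-10.0,
                           heavy_atom_count=25)  # eff -0.40
        for records in ([a, b], [b, a]):
            table = rank_compounds(records)
            assert list(table["compound_id"]) == ["A", "B"]

    def test_hit_flag_column(self, reference_records):
        table = rank_compounds(reference_records, HitCriterion())
        assert int(table["is_hit"].sum()) == 10


PDBQT_FIXTURE = """\
MODEL 1
REMARK VINA RESULT:     -11.4      0.000      0.000
ATOM      1  C   LIG A   1       0.000   0.000   0.000  0.00  0.00    +0.000 C
ENDMDL
MODEL 2
REMARK VINA RESULT:     -10.9      1.234      2.345
ENDMDL
MODEL 3
REMARK VINA RESULT:     -10.2      2.000      3.111
ENDMDL
"""

LOG_FIXTURE = """\
mode |   affinity | dist from best mode
     | (kcal/mol) | rmsd l.b.| rmsd u.b.
-----+------------+----------+----------
   1       -7.0      0.000      0.000
"""


class TestParseVinaResult:
    def test_pdbqt_three_modes(self):
        result = parse_vina_result(PDBQT_FIXTURE, dialect="pdbqt")
        assert [a for _, a in result.modes] == [-11.4, -10.9, -10.2]
        assert result.best_affinity == -11.4

    def test_log_single_mode(self):
        result = parse_vina_result(LOG_FIXTURE, dialect="log")
        assert result.best_affinity == -7.0
        assert len(result.modes) == 1

    def test_empty_file_is_parse_error(self):
        with pytest.raises(VinaParseError):
            parse_vina_result("", dialect="pdbqt")

    def test_unknown_dialect_rejected(self):
        with pytest.raises(VinaParseError):
            parse_vina_result(PDBQT_FIXTURE, dialect="xml")

    def test_non_numeric_affinity_reports_line(self):
        text = "REMARK VINA RESULT:     abc      0.000      0.000\n"
        with pytest.raises(VinaParseError, match="line 1"):
            parse_vina_result(text, dialect="pdbqt")

    def test_roundtrip_preserves_affinities(self, rng):
        affs = sorted(np.round(rng.uniform(-13, -5, size=5), 1))
        modes = DockingModeList(modes=[(i + 1, a) for i, a in enumerate(affs)])
        again = parse_vina_result(serialize_modes(modes), dialect="pdbqt")
        assert [a for _, a in again.modes] == list(affs)

    def test_mode_ordering_enforced(self):
        with pytest.raises(ValidationError):
            DockingModeList(modes=[(1, -9.0), (2, -11.0)])
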