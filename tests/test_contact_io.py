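import numpy as np
import pytest

from lossweb import connectance, read_contacts, read_contacts_wide, win_loss_summary, write_contacts
from lossweb.contact_io import ParseError, intraspecific_summary
from lossweb.synthetic import SyntheticSpec, generate_ensemble

from conftest import make_contacts

ABUNDANCE_3 = "species\tcolonies\nA\t10\nB\t8\nC\t5\n"


def _write(tmp_path, contacts_text, abundance_text=ABUNDANCE_3):
    cp = tmp_path / "contacts.tsv"
    ap = tmp_path / "abundance.tsv"
    cp.write_text(contacts_text)
    ap.write_text(abundance_text)
    return cp, ap


class TestReadLong:
    def test_three_species_table(self, tmp_path):
        text = (
            "species_a\tspecies_b\twins_a\twins_b\tdraws\n"
            "A\tB\t3\t1\t2\nA\tC\t0\t0\t0\nB\tC\t5\t0\t1\n"
        )
        cd = read_contacts(*_write(tmp_path, text))
        assert cd.species == ["A", "B", "C"]
        assert cd.wins[0, 1] == 3 and cd.wins[1, 0] == 1
        assert cd.draws[1, 2] == cd.draws[2, 1] == 1
        assert cd.n_contests(0, 2) == 0
        assert list(cd.abundance) == [10, 8, 5]

    def test_empty_contests_file(self, tmp_path):
        text = "species_a\tspecies_b\twins_a\twins_b\tdraws\n"
        ab = "species\tcolonies\nA\t3\nB\t4\n"
        cd = read_contacts(*_write(tmp_path, text, ab))
        assert cd.n_species == 2
        assert not cd.wins.any() and not cd.draws.any()

    def test_diagonal_row_records_intraspecific_events(self, tmp_path):
        text = "species_a\tspecies_b\twins_a\twins_b\tdraws\nA\tA\t2\t2\t1\n"
        cd = read_contacts(*_write(tmp_path, text))
        assert cd.wins[0, 0] == 2 and cd.draws[0, 0] == 1

    def test_negative_count_rejected(self, tmp_path):
        text = "species_a\tspecies_b\twins_a\twins_b\tdraws\nA\tB\t-1\t0\t0\n"
        with pytest.raises(ValueError, match="negative"):
            read_contacts(*_write(tmp_path, text))

    def test_unknown_species_names_line(self, tmp_path):
        text = "species_a\tspecies_b\twins_a\twins_b\tdraws\nA\tZ\t1\t0\t0\n"
        with pytest.raises(ParseError, match="line 2"):
            read_contacts(*_write(tmp_path, text))

    def test_duplicate_pair_rejected(self, tmp_path):
        text = (
            "species_a\tspecies_b\twins_a\twins_b\tdraws\n"
            "A\tB\t1\t0\t0\nB\tA\t0\t1\t0\n"
        )
        with pytest.raises(ParseError, match="duplicate"):
            read_contacts(*_write(tmp_path, text))


class TestWideDialect:
    def _write_wide(self, tmp_path, wins, draws):
        header = ",A,B,C\n"
        wp = tmp_path / "wins.csv"
        dp = tmp_path / "draws.csv"
        ap = tmp_path / "abundance.tsv"
        wp.write_text(header + "\n".join(f"{sp},{','.join(map(str, row))}"
                                         for sp, row in zip("ABC", wins)))
        dp.write_text(header + "\n".join(f"{sp},{','.join(map(str, row))}"
                                         for sp, row in zip("ABC", draws)))
        ap.write_text(ABUNDANCE_3)
        return wp, dp, ap

    def test_reads_matrices(self, tmp_path):
        wins = [[0, 3, 0], [1, 0, 5], [0, 0, 0]]
        draws = [[0, 2, 0], [2, 0, 1], [0, 1, 0]]
        cd = read_contacts_wide(*self._write_wide(tmp_path, wins, draws))
        assert cd.wins[0, 1] == 3 and cd.wins[1, 2] == 5
        assert cd.draws[0, 1] == 2

    def test_one_sided_draws_symmetrised(self, tmp_path):
        wins = [[0, 0, 0]] * 3
        draws = [[0, 2, 0], [0, 0, 0], [0, 0, 0]]  # only (A,B) recorded
        cd = read_contacts_wide(*self._write_wide(tmp_path, wins, draws))
        assert cd.draws[1, 0] == cd.draws[0, 1] == 2

    def test_conflicting_draws_rejected(self, tmp_path):
        wins = [[0, 0, 0]] * 3
        draws = [[0, 2, 0], [3, 0, 0], [0, 0, 0]]
        with pytest.raises(ValueError, match=r"\(A, B\)"):
            read_contacts_wide(*self._write_wide(tmp_path, wins, draws))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_write_read_round_trip(tmp_path, seed):
    cd = generate_ensemble(SyntheticSpec(S=6, seed=seed), 1)[0]
    cp, ap = tmp_path / "c.tsv", tmp_path / "a.tsv"
    write_contacts(cd, cp, ap)
    back = read_contacts(cp, ap, assemblage_id=cd.assemblage_id)
    assert back.species == cd.species
    assert np.array_equal(back.wins, cd.wins)
    assert np.array_equal(back.draws, cd.draws)
    assert np.array_equal(back.abundance, cd.abundance)


class TestValidation:
    def test_asymmetric_draws_rejected(self):
        draws = [[0, 1, 0], [2, 0, 0], [0, 0, 0]]
        with pytest.raises(ValueError, match=r"\(A, B\)"):
            make_contacts(np.zeros((3, 3), int), draws)

    def test_zero_abundance_rejected(self):
        with pytest.raises(ValueError, match="abundance"):
            make_contacts(np.zeros((2, 2), int), abundance=[5, 0])


class TestConnectance:
    def test_complete_graph(self):
        wins = [[0, 1, 1], [1, 0, 1], [1, 1, 0]]
        assert connectance(make_contacts(wins)) == 1.0

    def test_two_of_three_pairs(self):
        wins = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
        assert connectance(make_contacts(wins)) == pytest.approx(2 / 3)

    def test_empty_graph(self):
        assert connectance(make_contacts(np.zeros((5, 5), int))) == 0.0

    def test_draw_only_pair_counts(self):
        draws = [[0, 2], [2, 0]]
        assert connectance(make_contacts(np.zeros((2, 2), int), draws)) == 1.0

    def test_single_species_rejected(self):
        cd = make_contacts([[1]], abundance=[5], species=["A"])
        with pytest.raises(ValueError):
            connectance(cd)

    def test_invariant_under_species_permutation(self, rng):
        cd = generate_ensemble(SyntheticSpec(S=7, seed=3), 1)[0]
        perm = rng.permutation(7)
        permuted = make_contacts(
            cd.wins[np.ix_(perm, perm)], cd.draws[np.ix_(perm, perm)],
            cd.abundance[perm], [cd.species[i] for i in perm],
        )
        assert connectance(permuted) == pytest.approx(connectance(cd))


class TestWinLossSummary:
    def test_pair_rows_and_exclusions(self):
        wins = np.zeros((3, 3), int)
        wins[0, 1], wins[1, 0] = 3, 1
        wins[2, 2] = 4  # intraspecific only
        draws = np.zeros((3, 3), int)
        draws[0, 1] = draws[1, 0] = 2
        table = win_loss_summary(make_contacts(wins, draws))
        assert len(table) == 1  # non-interacting and diagonal excluded
        row = table.iloc[0]
        assert (row.wins_a, row.wins_b, row.draws, row.n) == (3, 1, 2, 6)
        intra = intraspecific_summary(make_contacts(wins, draws))
        assert intra.loc[2, "overgrowths"] == 4
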