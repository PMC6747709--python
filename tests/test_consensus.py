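"""Robust Z-scores, consensus ranking, shortlist selection, toy scorer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbmature.consensus import (FORMAL_CHARGE, HYDROPHOBICITY, consensus_z,
                                robust_z, select_top, toy_contact_score)
from nbmature.fixtures import gen_toy_complex
from nbmature.structio import parse_variant


class TestRobustZ:
    def test_hand_computed_outlier(self):
        z = robust_z([1, 2, 3, 4, 100])
        # median 3, MAD 1 -> Z(100) = 97 / 1.4826
        assert z[-1] == pytest.approx(97 / 1.4826, abs=1e-6)
        assert z[-1] == pytest.approx(65.42, abs=0.01)

    def test_constant_column_all_zero(self):
        assert np.all(robust_z([5.0, 5.0, 5.0]) == 0)

    def test_mad_zero_falls_back_to_sd(self):
        # MAD = 0 (majority identical) but SD > 0
        z = robust_z([1.0, 1.0, 1.0, 10.0])
        assert np.all(np.isfinite(z)) and z[-1] > 0

    @given(st.lists(st.integers(-1000, 1000), min_size=3, max_size=40),
           st.floats(0.1, 50), st.floats(-100, 100))
    @settings(max_examples=200, deadline=None)
    def test_positive_affine_invariance(self, values, a, b):
        s = np.array(values, dtype=float) / 10.0
        np.testing.assert_allclose(robust_z(a * s + b), robust_z(s),
                                   rtol=1e-8, atol=1e-8)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            robust_z([1.0])


def brute_force_consensus_ranks(matrix: pd.DataFrame) -> list[str]:
    """Independent reimplementation: per-column median/MAD Z, mean, sort."""
    zs = {}
    for lab in matrix.index:
        acc = []
        for col in matrix.columns:
            s = matrix[col].to_numpy(dtype=float)
            med = float(np.median(s))
            mad = float(np.median(np.abs(s - med)))
            scale = 1.4826 * mad if mad else float(np.std(s, ddof=1))
            acc.append((matrix.loc[lab, col] - med) / scale if scale else 0.0)
        zs[lab] = sum(acc) / len(acc)
    return sorted(zs, key=lambda lab: (zs[lab], lab))


class TestConsensus:
    def test_single_scorer_equals_robust_z(self):
        m = pd.DataFrame({"only": [1.0, 2.0, 8.0]}, index=list("abc"))
        cr = consensus_z(m)
        np.testing.assert_allclose(cr.consensus.to_numpy(),
                                   robust_z(m["only"].to_numpy()))

    def test_affine_copy_scorer_changes_nothing(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        m1 = pd.DataFrame({"s1": base}, index=[f"v{i}" for i in range(30)])
        m2 = m1.assign(s2=3.0 * base + 7.0)
        np.testing.assert_allclose(consensus_z(m2).consensus.to_numpy(),
                                   consensus_z(m1).consensus.to_numpy(),
                                   rtol=1e-10)

    def test_random_matrix_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("xyz"),
                         index=[f"v{i:02d}" for i in range(50)])
        assert list(consensus_z(m).ranked.index) == brute_force_consensus_ranks(m)

    def test_nan_cell_names_variant(self):
        m = pd.DataFrame({"s": [1.0, np.nan, 3.0]}, index=["a", "bad", "c"])
        with pytest.raises(ValueError, match="bad"):
            consensus_z(m)

    def test_per_scorer_affine_invariance_of_ranking(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("pqr"),
                         index=[f"v{i}" for i in range(20)])
        m2 = pd.DataFrame({"p": 2 * m["p"] + 1, "q": 0.5 * m["q"] - 9,
                           "r": 10 * m["r"]}, index=m.index)
        assert list(consensus_z(m).ranked.index) == list(consensus_z(m2).ranked.index)


class TestSelectTop:
    def _result(self, zvals, labels):
        m = pd.DataFrame({"s": zvals}, index=labels)
        return consensus_z(m)

    def test_all_nonnegative_empty(self):
        # raw scores rising with index: top half negative Z, rest positive;
        # max_z below the minimum Z leaves nothing
        cr = self._result(np.arange(10.0), [f"v{i}" for i in range(10)])
        assert select_top(cr, max_z=min(cr.consensus) - 1) == []

    def test_truncation_and_threshold(self):
        rng = np.random.default_rng(5)
        cr = self._result(rng.normal(size=40), [f"v{i:02d}" for i in range(40)])
        out = select_top(cr, n=5, max_z=0.0)
        assert len(out) == 5
        assert all(cr.consensus[lab] < 0 for lab in out)

    def test_monotone_in_max_z(self):
        rng = np.random.default_rng(6)
        cr = self._result(rng.normal(size=30), [f"v{i:02d}" for i in range(30)])
        sets = [set(select_top(cr, n=30, max_z=z)) for z in (-1.0, 0.0, 1.0)]
        assert sets[0] <= sets[1] <= sets[2]

    def test_per_site_cap_counting_oracle(self):
        rng = np.random.default_rng(8)
        labels = [f"{wt}{pos}{mut}" for pos, wt in [(55, "S"), (107, "G"), (108, "T")]
                  for mut in "ADEFHIKLMNQRVWY" if mut != wt]
        cr = self._result(rng.normal(size=len(labels)), labels)
        out = select_top(cr, n=len(labels), max_z=10.0, per_site_cap=2)
        counts = {}
        for lab in out:
            for p in parse_variant(lab).positions:
                counts[p] = counts.get(p, 0) + 1
        assert counts and all(c <= 2 for c in counts.values())

    def test_wt_row_never_selected(self):
        cr = self._result([0.0, -5.0, 5.0], ["a", "WT", "b"])
        assert "WT" not in select_top(cr, max_z=10.0)


class TestToyContactScore:
    def test_no_contacts_zero(self):
        s = gen_toy_complex(5, [], seed=0)
        assert toy_contact_score(s, parse_variant("WT"), "A", "B") == 0.0

    def test_empty_variant_identity(self):
        s = gen_toy_complex(10, [4], seed=1)
        e0 = toy_contact_score(s, parse_variant("WT"), "A", "B")
        assert toy_contact_score(s, parse_variant(""), "A", "B") == e0

    def test_charge_flip_hand_computed(self):
        # K opposite D in contact: mutating K -> E flips q from +1 to -1,
        # so the charge term goes from -w_q to +w_q; the hydrophobic term
        # changes by the h-scale difference of K vs E against D.
        s = gen_toy_complex(6, [3], seed=0, sequence={3: "K"},
                            partner_sequence=["D"])
        w_q, w_h = 2.0, 1.0
        e_wt = toy_contact_score(s, parse_variant("WT"), "A", "B",
                                 w_charge=w_q, w_hydrophobic=w_h)
        e_mut = toy_contact_score(s, parse_variant("K3E"), "A", "B",
                                  w_charge=w_q, w_hydrophobic=w_h)
        h = HYDROPHOBICITY
        expected_delta = ((FORMAL_CHARGE["E"] - FORMAL_CHARGE["K"]) *
                          FORMAL_CHARGE["D"] * w_q
                          - (h["E"] - h["K"]) * h["D"] * w_h)
        assert e_mut - e_wt == pytest.approx(expected_delta, abs=1e-9)

    def test_additive_over_independent_pairs(self):
        s1 = gen_toy_complex(20, [5], seed=2, sequence={5: "K"},
                             partner_sequence=["D"])
        s2 = gen_toy_complex(20, [15], seed=2, sequence={15: "L"},
                             partner_sequence=["I"])
        s12 = gen_toy_complex(20, [5, 15], seed=2, sequence={5: "K", 15: "L"},
                              partner_sequence=["D", "I"])
        wt = parse_variant("WT")
        e1 = toy_contact_score(s1, wt, "A", "B")
        e2 = toy_contact_score(s2, wt, "A", "B")
        e12 = toy_contact_score(s12, wt, "A", "B")
        assert e12 == pytest.approx(e1 + e2, abs=1e-9)

    def test_variant_off_chain_errors(self):
        s = gen_toy_complex(5, [2], seed=0)
        with pytest.raises(KeyError):
            toy_contact_score(s, parse_variant("G99W"), "A", "B")
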