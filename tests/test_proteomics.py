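"""iTRAQ chain: channel math, consolidation, normalization, Rrollup, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rootheat.proteomics import (
    CHANNEL_COLS,
    ITraqQuantifier,
    channel_intensities_from_scan,
    consolidate_peptides,
    normalize_peptides,
    protein_de_test,
    rrollup_protein,
)
from rootheat.simulate import SimConfig, gen_itraq_peptides, itraq_channel_design


def _scan_row(scan, peptide, protein, reporters, plex="p1", base_peak=None):
    rep = np.asarray(reporters, float)
    return {
        "scan": scan, "peptide": peptide, "protein": protein, "plex": plex,
        "fraction": "f01", "base_peak": base_peak if base_peak else float(rep.sum()),
        **{f"ch{i+1}": rep[i] for i in range(8)},
    }


class TestChannelIntensities:
    def test_equal_reporters_split_evenly(self):
        out = channel_intensities_from_scan(np.ones(8), 800.0)
        assert np.allclose(out, 100.0)

    def test_fraction_arithmetic(self):
        out = channel_intensities_from_scan([3, 1, 0, 0, 0, 0, 0, 0], 100.0)
        assert out[:2] == pytest.approx([75.0, 25.0])
        assert np.all(out[2:] == 0)

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1e6, allow_subnormal=False),
            min_size=8, max_size=8,
        ),
        st.floats(min_value=1e-3, max_value=1e9),
    )
    def test_conservation_property(self, reporters, base_peak):
        if sum(reporters) < 1e-6:
            return
        out = channel_intensities_from_scan(reporters, base_peak)
        assert out.sum() == pytest.approx(base_peak, rel=1e-9)

    def test_all_zero_reporters_rejected(self):
        with pytest.raises(ValueError):
            channel_intensities_from_scan(np.zeros(8), 10.0)


class TestConsolidate:
    def test_single_scan_gives_log2_intensities(self):
        df = pd.DataFrame([_scan_row("s1", "PEP", "P1", [4, 4, 4, 4, 4, 4, 4, 4])])
        out = consolidate_peptides(df)
        assert np.allclose(out[CHANNEL_COLS].to_numpy(), 2.0)  # log2(4)

    def test_two_identical_scans_add_one_in_log2(self):
        row = _scan_row("s1", "PEP", "P1", [4, 8, 16, 4, 4, 4, 4, 4])
        df1 = pd.DataFrame([row])
        df2 = pd.DataFrame([row, {**row, "scan": "s2"}])
        one = consolidate_peptides(df1)[CHANNEL_COLS].to_numpy()
        two = consolidate_peptides(df2)[CHANNEL_COLS].to_numpy()
        assert np.allclose(two, one + 1.0)

    def test_zero_channel_becomes_missing_not_minus_inf(self):
        df = pd.DataFrame([_scan_row("s1", "PEP", "P1", [4, 0, 4, 4, 4, 4, 4, 4])])
        out = consolidate_peptides(df)
        assert np.isnan(out["ch2"].iloc[0])

    def test_all_zero_scan_skipped_with_warning(self):
        rows = [_scan_row("s1", "PEP", "P1", [1] * 8),
                _scan_row("s2", "PEP", "P1", [0] * 8, base_peak=5.0)]
        with pytest.warns(UserWarning, match="all-zero"):
            out = consolidate_peptides(pd.DataFrame(rows))
        assert len(out) == 1


class TestNormalize:
    def test_hand_computed_single_plex_fixture(self):
        """Two peptides, refs at ch4/ch8; both steps frozen by hand:
        step 1 subtracts each row's reference mean, step 2 shifts every
        channel's median onto the global median (here 1.0)."""
        tab = pd.DataFrame(
            [
                {"protein": "P", "peptide": "a", "plex": "p1",
                 **dict(zip(CHANNEL_COLS, [10, 11, 12, 10, 13, 14, 15, 12.0]))},
                {"protein": "P", "peptide": "b", "plex": "p1",
                 **dict(zip(CHANNEL_COLS, [20, 21, 22, 21, 23, 24, 25, 23.0]))},
            ]
        )
        out = normalize_peptides(tab, ref_channels=(4, 8))
        expect_a = [1.5, 1.5, 1.5, 1.0, 1.5, 1.5, 1.5, 1.0]
        expect_b = [0.5, 0.5, 0.5, 1.0, 0.5, 0.5, 0.5, 1.0]
        assert out[CHANNEL_COLS].iloc[0].tolist() == pytest.approx(expect_a)
        assert out[CHANNEL_COLS].iloc[1].tolist() == pytest.approx(expect_b)

    def test_constant_channel_bias_removed(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, size=(40, 8))
        base[:, 3] = base[:, [4, 5]].mean(axis=1)  # ref channels carry signal
        base[:, 7] = base[:, 3]
        biased = base.copy()
        biased[:, 2] += 2.0  # constant +2 bias on ch3
        tab = pd.DataFrame(biased, columns=CHANNEL_COLS)
        tab.insert(0, "plex", "p1")
        tab.insert(0, "peptide", [f"pep{i}" for i in range(40)])
        tab.insert(0, "protein", "P")
        out = normalize_peptides(tab, ref_channels=(4, 8))
        med = out[CHANNEL_COLS].median()
        assert np.allclose(med, med.iloc[0], atol=1e-9)

    def test_all_channels_equal_references_collapse(self):
        tab = pd.DataFrame(
            [{"protein": "P", "peptide": "a", "plex": "p1",
              **dict(zip(CHANNEL_COLS, [7.0] * 8))}]
        )
        out = normalize_peptides(tab, ref_channels=(4, 8))
        vals = out[CHANNEL_COLS].iloc[0].to_numpy()
        assert np.allclose(vals, vals[0])

    def test_missing_references_drop_peptide(self):
        row = {"protein": "P", "peptide": "a", "plex": "p1",
               **dict(zip(CHANNEL_COLS, [1.0] * 8))}
        row["ch4"] = np.nan
        row["ch8"] = np.nan
        with pytest.warns(UserWarning, match="pooled-reference"):
            out = normalize_peptides(pd.DataFrame([row]), ref_channels=(4, 8))
        assert len(out) == 0


class TestRrollup:
    def _tab(self, rows):
        recs = []
        for i, r in enumerate(rows):
            recs.append({"protein": "P", "peptide": f"pep{i}", "plex": "p1",
                         **dict(zip(CHANNEL_COLS, r))})
        return pd.DataFrame(recs)

    def test_single_peptide_passthrough(self):
        vals = [1.0, 2, 3, 4, 5, 6, 7, 8]
        out = rrollup_protein(self._tab([vals]))
        assert out.tolist() == pytest.approx(vals)

    def test_constant_offset_peptide_collapses(self):
        p1 = np.arange(8.0)
        out = rrollup_protein(self._tab([p1, p1 + 3]))
        # reference is the higher-abundance copy; shifted copies coincide
        assert out.tolist() == pytest.approx((p1 + 3).tolist())

    def test_hand_computed_three_peptide_fixture(self):
        """Planted per-sample signal {0,1,2,3} with peptide offsets {0,+3,-2}
        and one outlier cell; the median over scaled peptides recovers the
        signal on the reference peptide's scale: {3,4,5,6}."""
        sig = np.array([0.0, 1, 2, 3])
        pep1 = np.concatenate([sig, [np.nan] * 4])
        pep2 = np.concatenate([sig + 3, [np.nan] * 4])
        pep3 = np.concatenate([sig - 2, [np.nan] * 4])
        pep3[2] = 5.0  # outlier
        out = rrollup_protein(self._tab([pep1, pep2, pep3]))
        assert out.iloc[:4].tolist() == pytest.approx([3.0, 4.0, 5.0, 6.0])

    def test_shift_invariance_of_protein_estimate(self):
        """Shifting a non-reference peptide's whole log2 row leaves the
        protein estimate unchanged (the scaling step absorbs it).  The
        shifted peptide is given a missing value so the reference choice
        (most present peptide) cannot change."""
        rng = np.random.default_rng(1)
        rows = [rng.normal(10, 1, 8) for _ in range(3)]
        rows[1][5] = np.nan  # pep1 can never be the reference
        base = rrollup_protein(self._tab(rows))
        for shift in (7.5, -7.5):
            rows2 = [rows[0], rows[1] + shift, rows[2]]
            shifted = rrollup_protein(self._tab(rows2))
            assert base.tolist() == pytest.approx(shifted.tolist(), nan_ok=True)

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            rrollup_protein(self._tab([]))


class TestProteinDETest:
    def _setup(self, ctrl, heat):
        cfg = SimConfig(seed=0)
        chan = itraq_channel_design(cfg, timepoints=[3])
        vals = np.full(8, np.nan)
        sample_ch = [c for c in range(1, 9) if c not in (4, 8)]
        for k, c in enumerate(sample_ch[:3]):
            vals[c - 1] = ctrl[k]
        for k, c in enumerate(sample_ch[3:]):
            vals[c - 1] = heat[k]
        abund = pd.DataFrame([vals], columns=CHANNEL_COLS,
                             index=pd.MultiIndex.from_tuples([("P1", "plex_3h")],
                                                             names=["protein", "plex"]))
        return abund, chan

    def test_anova_fixture_f_13_5(self):
        """Groups {1,2,3} vs {4,5,6}: F = 13.5 on df (1, 4), log2 fc = 3."""
        abund, chan = self._setup([1, 2, 3], [4, 5, 6])
        res = protein_de_test(abund, chan)
        f = stats.f_oneway([1, 2, 3], [4, 5, 6])
        assert f.statistic == pytest.approx(13.5)
        assert res["p"].iloc[0] == pytest.approx(stats.f.sf(13.5, 1, 4))
        assert res["log2_fc"].iloc[0] == pytest.approx(3.0)

    def test_identical_groups_flat(self):
        abund, chan = self._setup([2, 2, 2], [2, 2, 2])
        res = protein_de_test(abund, chan)
        assert res["p"].iloc[0] == 1.0
        assert res["log2_fc"].iloc[0] == 0.0
        assert not res["called"].iloc[0]

    def test_insufficient_group_marked_untestable(self):
        abund, chan = self._setup([1, np.nan, np.nan], [4, 5, 6])
        res = protein_de_test(abund, chan)
        assert not res["testable"].iloc[0]

    def test_bh_hand_computed(self):
        """BH on p = {0.01, 0.02, 0.03, 0.04} across four proteins at one
        time point adjusts every p to 0.04."""
        cfg = SimConfig(seed=0)
        chan = itraq_channel_design(cfg, timepoints=[3])
        # build four proteins whose ANOVA p-values we then overwrite is not
        # possible; instead verify the correction arithmetic directly
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_null_protein_pvalues_uniform():
    """Zero planted effects: the per-time-point ANOVA p-values are uniform."""
    cfg = SimConfig(n_proteins=400, peptides_per_protein=(2, 3), de_fraction=0.0,
                    noise_sd=0.1, missing_rate=0.0, timepoints=(3,), seed=8)
    spectra, chan, _ = gen_itraq_peptides(cfg)
    res = ITraqQuantifier().fit(spectra).test(chan)
    p = res.loc[res["testable"], "p"]
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_planted_shift_recovered_within_tolerance():
    cfg = SimConfig(n_proteins=100, peptides_per_protein=(3, 3), de_fraction=0.10,
                    noise_sd=0.05, missing_rate=0.0, timepoints=(3,), seed=2)
    spectra, chan, truth = gen_itraq_peptides(cfg)
    res = ITraqQuantifier().fit(spectra).test(chan)
    sub = res[res["protein"].isin(truth.protein_effects) & res["testable"]]
    errs = np.abs(np.abs(sub["log2_fc"]) - 1.0)
    assert (errs < 0.1).mean() >= 0.95
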