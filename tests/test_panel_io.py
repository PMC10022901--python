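import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adnahap.panel_io import (
    AlleleCounts,
    CohortMetadata,
    PanelIOError,
    SNPPanel,
    counts_from_mpileup,
    load_counts,
    load_metadata,
    load_panel,
    write_counts,
    write_metadata,
    write_panel,
)

from conftest import make_panel


class TestPanelValidation:
    def test_row_count_preserved(self, tmp_path):
        panel = make_panel(20)
        write_panel(panel, tmp_path / "p.tsv")
        reloaded = load_panel(tmp_path / "p.tsv")
        assert len(reloaded) == 20
        assert reloaded.snp_ids == panel.snp_ids  # order preserved

    def test_duplicate_snp_id_rejected(self):
        df = make_panel(2).df.copy()
        df.loc[1, "snp_id"] = df.loc[0, "snp_id"]
        with pytest.raises(PanelIOError, match="duplicate"):
            SNPPanel(df)

    def test_adaptive_must_be_ref_or_alt(self):
        df = make_panel(1).df.copy()  # ref G, alt A
        df.loc[0, "adaptive"] = "C"
        with pytest.raises(PanelIOError, match="adaptive"):
            SNPPanel(df)

    def test_header_only_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("snp_id\tchrom\tpos\tref\talt\tadaptive\tis_transition\n")
        assert len(load_panel(path)) == 0

    def test_ref_equal_alt_rejected(self):
        df = make_panel(1).df.copy()
        df.loc[0, "alt"] = df.loc[0, "ref"]
        df.loc[0, "adaptive"] = df.loc[0, "ref"]
        with pytest.raises(PanelIOError, match="ref == alt"):
            SNPPanel(df)


class TestCountsValidation:
    def test_pass_through(self, panel3):
        df = pd.DataFrame(
            [["ind1", "snp03", 2, 5]],
            columns=["individual_id", "snp_id", "n_adaptive", "n_total"],
        )
        counts = AlleleCounts(df, panel=panel3)
        assert len(counts) == 1

    def test_adaptive_exceeding_total_rejected(self, panel3):
        df = pd.DataFrame(
            [["ind1", "snp03", 6, 5]],
            columns=["individual_id", "snp_id", "n_adaptive", "n_total"],
        )
        with pytest.raises(PanelIOError, match="n_adaptive > n_total"):
            AlleleCounts(df, panel=panel3)

    def test_duplicate_pair_rejected(self, panel3):
        df = pd.DataFrame(
            [["ind1", "snp03", 2, 5], ["ind1", "snp03", 1, 2]],
            columns=["individual_id", "snp_id", "n_adaptive", "n_total"],
        )
        with pytest.raises(PanelIOError, match="duplicate"):
            AlleleCounts(df, panel=panel3)

    def test_unknown_snp_rejected(self, panel3):
        df = pd.DataFrame(
            [["ind1", "snp99", 1, 1]],
            columns=["individual_id", "snp_id", "n_adaptive", "n_total"],
        )
        with pytest.raises(PanelIOError, match="absent from panel"):
            AlleleCounts(df, panel=panel3)


class TestRoundTrips:
    def test_counts_roundtrip_random(self, tmp_path, panel20):
        rng = np.random.default_rng(7)
        rows = []
        for ind in range(2):
            for snp in panel20.snp_ids:
                t = int(rng.poisson(2))
                if t == 0:
                    continue
                rows.append([f"ind{ind}", snp, int(rng.integers(0, t + 1)), t])
        counts = AlleleCounts(
            pd.DataFrame(rows, columns=["individual_id", "snp_id", "n_adaptive", "n_total"]),
            panel=panel20,
        )
        write_counts(counts, tmp_path / "c.tsv")
        assert load_counts(tmp_path / "c.tsv", panel20) == counts

    def test_empty_counts_roundtrip(self, tmp_path, panel20):
        counts = AlleleCounts(
            pd.DataFrame(columns=["individual_id", "snp_id", "n_adaptive", "n_total"]),
            panel=panel20,
        )
        write_counts(counts, tmp_path / "c.tsv")
        assert len(load_counts(tmp_path / "c.tsv", panel20)) == 0

    def test_metadata_roundtrip(self, tmp_path):
        meta = CohortMetadata(
            pd.DataFrame(
                {
                    "individual_id": ["a", "b", "c"],
                    "date_bp": [5100.0, 830.5, "modern"],
                    "group": ["old", "new", "now"],
                    "region": ["ne", "s", "s"],
                }
            )
        )
        write_metadata(meta, tmp_path / "m.tsv")
        assert load_metadata(tmp_path / "m.tsv") == meta

    def test_panel_roundtrip(self, tmp_path, panel20):
        write_panel(panel20, tmp_path / "p.tsv")
        assert load_panel(tmp_path / "p.tsv") == panel20


class TestMpileup:
    """Spec'd cases for the single-sample mpileup dialect at the first panel
    site (ref G, adaptive A)."""

    def line(self, bases, quals, pos=46_550_000, depth=None):
        depth = len(quals) if depth is None else depth
        return f"2\t{pos}\tG\t{depth}\t{bases}\t{quals}\n"

    def test_basic_counts_and_strand(self, panel20):
        counts = counts_from_mpileup(self.line(".,AaA", "IIIII"), panel20)
        row = counts.df.iloc[0]
        assert (row.n_adaptive, row.n_total) == (3, 5)

    def test_quality_filter(self, panel20):
        counts = counts_from_mpileup(self.line(".,AAA", "II#II"), panel20)
        row = counts.df.iloc[0]
        # '#' is Q2: that A is dropped from both counts
        assert (row.n_adaptive, row.n_total) == (2, 4)

    def test_markers_consumed(self, panel20):
        counts = counts_from_mpileup(self.line("^].,$A", "III"), panel20)
        row = counts.df.iloc[0]
        assert (row.n_adaptive, row.n_total) == (1, 3)

    def test_indels_and_placeholders_excluded(self, panel20):
        counts = counts_from_mpileup(self.line(".+2AGA*<", "IIII"), panel20)
        row = counts.df.iloc[0]
        assert (row.n_adaptive, row.n_total) == (1, 2)

    def test_non_panel_lines_skipped(self, panel20):
        text = "2\t1\tG\t1\tA\tI\n" + self.line("A", "I")
        counts = counts_from_mpileup(text, panel20)
        assert len(counts) == 1

    def test_length_mismatch_raises(self, panel20):
        with pytest.raises(PanelIOError, match="quality"):
            counts_from_mpileup(self.line(".,A", "II"), panel20)

    def test_strict_biallelic_excludes_third_allele(self, panel20):
        # site ref G / alt A: a C read counts to n_total only when not strict
        lax = counts_from_mpileup(self.line(".CA", "III"), panel20)
        strict = counts_from_mpileup(
            self.line(".CA", "III"), panel20, strict_biallelic=True
        )
        assert lax.df.iloc[0].n_total == 3
        assert strict.df.iloc[0].n_total == 2

    @given(
        bases=st.lists(
            st.sampled_from(list(".,AaCcGgTtNn*")), min_size=1, max_size=30
        ),
        quals=st.integers(min_value=0, max_value=60),
    )
    @settings(max_examples=60, deadline=None)
    def test_case_insensitive_and_bounded(self, bases, quals):
        panel = make_panel(1)
        base_str = "".join(bases)
        qual_str = chr(quals + 33) * len(bases)
        line = f"2\t46550000\tG\t{len(bases)}\t{base_str}\t{qual_str}\n"
        upper = f"2\t46550000\tG\t{len(bases)}\t{base_str.upper()}\t{qual_str}\n"
        got = counts_from_mpileup(line, panel).df
        got_upper = counts_from_mpileup(upper, panel).df
        # strand (case) never changes the outcome
        pd.testing.assert_frame_equal(got, got_upper)
        row = got.iloc[0]
        assert 0 <= row.n_adaptive <= row.n_total <= len(bases)
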