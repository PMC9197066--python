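"""Summary-statistics I/O: dialects, derivation, filtering, round-trips."""

import gzip

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sumgene.sumstats_io import (
    SumstatsFormatError,
    filter_variants,
    p_z_consistent,
    read_gene_regions,
    read_sumstats,
    write_results,
    write_sumstats,
    z_magnitude_from_p,
)


def _frame(n=5, rng=None, **over):
    rng = rng or np.random.default_rng(1)
    df = pd.DataFrame(
        {
            "SNP": [f"rs{k}" for k in range(n)],
            "CHR": "1",
            "POS": np.arange(1, n + 1) * 1000,
            "A1": "A",
            "A2": "G",
            "BETA": rng.normal(0, 0.1, n),
            "SE": rng.uniform(0.02, 0.1, n),
            "EAF": rng.uniform(0.01, 0.99, n),
            "N": 10000,
        }
    )
    for k, v in over.items():
        df[k] = v
    return df


def test_z_derived_from_beta_se(tmp_path):
    path = tmp_path / "s.tsv"
    _frame(3, BETA=[0.1, -0.2, 0.0], SE=[0.05, 0.1, 0.1]).to_csv(
        path, sep="\t", index=False
    )
    out = read_sumstats(path)
    assert out["z"].to_numpy() == pytest.approx([2.0, -2.0, 0.0])
    assert out["p"].iloc[2] == 1.0  # two-sided tail of z = 0


def test_eaf_folded_to_maf(tmp_path):
    path = tmp_path / "s.tsv"
    _frame(2, EAF=[0.9, 0.2]).to_csv(path, sep="\t", index=False)
    out = read_sumstats(path)
    assert out["maf"].to_numpy() == pytest.approx([0.1, 0.2])


def test_missing_required_column_raises(tmp_path):
    path = tmp_path / "s.tsv"
    _frame(2).drop(columns=["A1"]).to_csv(path, sep="\t", index=False)
    with pytest.raises(SumstatsFormatError):
        read_sumstats(path)


def test_nonfinite_records_rejected(tmp_path):
    path = tmp_path / "s.tsv"
    _frame(4, SE=[0.05, np.nan, 0.0, 0.1]).to_csv(path, sep="\t", index=False)
    out = read_sumstats(path)
    assert len(out) == 2


def test_custom_dialect(tmp_path):
    df = _frame(2).rename(columns={"SNP": "MarkerName", "BETA": "Effect"})
    path = tmp_path / "s.tsv"
    df.to_csv(path, sep="\t", index=False)
    out = read_sumstats(path, dialect={"variant_id": "MarkerName", "beta": "Effect"})
    assert list(out["variant_id"]) == ["rs0", "rs1"]


def test_round_trip_identity(tmp_path, rng):
    path1, path2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    _frame(1000, rng=rng).to_csv(path1, sep="\t", index=False)
    first = read_sumstats(path1)
    write_sumstats(first, path2)
    second = read_sumstats(path2)
    for col in ("z", "p", "maf", "beta", "se"):
        assert second[col].to_numpy() == pytest.approx(
            first[col].to_numpy(), rel=1e-9
        )
    assert list(second["variant_id"]) == list(first["variant_id"])


class TestFilterVariants:
    def test_mac_threshold_definition(self):
        df = _frame(3, MAC=[4, 5, 6])
        st = read_sumstats_frame(df)
        out = filter_variants(st, min_mac=5)
        assert len(out) == 2

    def test_maf_window_empty_result_is_not_error(self):
        st = read_sumstats_frame(_frame(3, EAF=[0.3, 0.3, 0.3]))
        out = filter_variants(st, min_mac=0, max_maf=0.01)
        assert out.empty

    def test_matches_brute_force_row_scan(self, rng):
        df = _frame(10_000, rng=rng, MAC=rng.integers(0, 50, 10_000))
        st = read_sumstats_frame(df)
        out = filter_variants(st, min_mac=5, max_maf=0.4, min_maf=0.01)
        expect = [
            row.variant_id
            for row in st.itertuples()
            if row.mac >= 5 and 0.01 < row.maf < 0.4
        ]
        assert list(out["variant_id"]) == expect

    def test_idempotent_and_subset(self, rng):
        st = read_sumstats_frame(_frame(500, rng=rng, MAC=rng.integers(0, 20, 500)))
        once = filter_variants(st, min_mac=5, max_maf=0.3)
        twice = filter_variants(once, min_mac=5, max_maf=0.3)
        pd.testing.assert_frame_equal(once, twice)
        assert set(once["variant_id"]) <= set(st["variant_id"])


def read_sumstats_frame(df):
    """Round a raw frame through the reader (via an in-memory temp file)."""
    import io

    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return read_sumstats(buf)


class TestGeneRegions:
    def test_pair_format(self, tmp_path):
        path = tmp_path / "g.tsv"
        pd.DataFrame(
            {"gene_id": ["G1"] * 3 + ["G2"], "variant_id": ["a", "b", "c", "d"]}
        ).to_csv(path, sep="\t", index=False)
        regions = read_gene_regions(path)
        assert [r.gene_id for r in regions] == ["G1", "G2"]
        assert len(regions[0]) == 3

    def test_duplicate_variant_in_gene_raises(self, tmp_path):
        path = tmp_path / "g.tsv"
        pd.DataFrame(
            {"gene_id": ["G1", "G1"], "variant_id": ["a", "a"]}
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(SumstatsFormatError):
            read_gene_regions(path)

    def test_range_format_matches_position_scan(self, tmp_path, rng):
        st = read_sumstats_frame(_frame(200, rng=rng))
        path = tmp_path / "g.tsv"
        pd.DataFrame(
            {"gene_id": ["G1"], "chrom": ["1"], "start": [5000], "end": [50000]}
        ).to_csv(path, sep="\t", index=False)
        regions = read_gene_regions(path, st)
        expect = st[(st["pos"] >= 5000) & (st["pos"] <= 50000)]["variant_id"]
        assert regions[0].variant_ids == list(expect)

    def test_empty_gene_excluded(self, tmp_path, rng):
        st = read_sumstats_frame(_frame(10, rng=rng))
        path = tmp_path / "g.tsv"
        pd.DataFrame(
            {"gene_id": ["G1"], "chrom": ["1"], "start": [10**8], "end": [2 * 10**8]}
        ).to_csv(path, sep="\t", index=False)
        assert read_gene_regions(path, st) == []

    def test_variants_missing_from_stats_flagged(self, tmp_path, rng):
        st = read_sumstats_frame(_frame(3, rng=rng))
        path = tmp_path / "g.tsv"
        pd.DataFrame(
            {"gene_id": ["G1"] * 2, "variant_id": ["rs0", "novel"]}
        ).to_csv(path, sep="\t", index=False)
        regions = read_gene_regions(path, st)
        assert regions[0].flagged_missing == ["novel"]
        assert len(regions[0]) == 2  # retained in the definition


class TestWriteResults:
    def _result(self, gene_id, p, chrom="1", pos=100):
        from sumgene.omnibus import GeneResult

        return GeneResult(
            gene_id=gene_id, p_lattice={("SKAT", 1, 0): p},
            p_method={"SKAT": p}, p_overall=p, m_used=3,
            flags={"approximated"}, chrom=chrom, start_pos=pos,
        )

    def test_single_gene_row_and_header(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_results([self._result("G1", 0.02)], path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 2
        assert lines[0].startswith("gene_id")

    def test_round_trip_lossless_at_1e6_relative(self, tmp_path):
        path = tmp_path / "r.tsv"
        p = 0.012345678901
        write_results([self._result("G1", p)], path)
        back = pd.read_csv(path, sep="\t")
        assert back["p_overall"].iloc[0] == pytest.approx(p, rel=1e-6)

    def test_sorted_by_genomic_position(self, tmp_path):
        path = tmp_path / "r.tsv"
        rs = [self._result("B", 0.1, pos=500), self._result("A", 0.2, pos=100)]
        write_results(rs, path)
        back = pd.read_csv(path, sep="\t")
        assert list(back["gene_id"]) == ["A", "B"]

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_results([], tmp_path / "r.tsv")


def test_p_z_mutual_consistency(rng):
    z = rng.normal(0, 3, 200)
    p = stats.norm.sf(np.abs(z)) * 2
    assert p_z_consistent(p, z).all()
    back = z_magnitude_from_p(p)
    assert back == pytest.approx(np.abs(z), rel=1e-6)


def test_gzip_input_supported(tmp_path, rng):
    path = tmp_path / "s.tsv.gz"
    with gzip.open(path, "wt") as fh:
        _frame(5, rng=rng).to_csv(fh, sep="\t", index=False)
    assert len(read_sumstats(path)) == 5
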