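"""Peak I/O, overlap clustering, gene assignment and motif scanning."""

import numpy as np
import pytest

from helpers import brute_force_clusters, regex_motif_count

from cofbal.cistrome import (
    Cistrome,
    MotifPattern,
    Peak,
    assign_peaks_to_genes,
    centre_distance_profile,
    cluster_peaks,
    count_motif_matches,
    occupancy_signature_counts,
    promoter_fraction,
    read_peaks,
    signature_label,
    write_peaks,
)


def _cistrome(label, centres, chrom="chr1", score=1.0, halfwidth=50):
    return Cistrome(label, [
        Peak(chrom, c - halfwidth, c + halfwidth, c, score, f"{label}{i}")
        for i, c in enumerate(centres)
    ])


class TestPeakIO:
    def test_narrowpeak_summit_offset_gives_absolute_centre(self, tmp_path):
        path = tmp_path / "x.narrowPeak"
        path.write_text("chr1\t1000\t1200\tp1\t0\t.\t8.5\t-1\t-1\t50\n")
        c = read_peaks(path, "narrowPeak", factor="F")
        assert c.peaks[0].centre == 1050
        assert c.peaks[0].score == 8.5

    def test_narrowpeak_missing_summit_falls_back_to_midpoint(self, tmp_path):
        path = tmp_path / "x.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t0\t.\t1\t-1\t-1\t-1\n")
        assert read_peaks(path, "narrowPeak").peaks[0].centre == 150

    def test_bed6_centre_is_floored_midpoint(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t100\t201\tp1\t3\t+\n")
        assert read_peaks(path, "bed6").peaks[0].centre == 150

    def test_malformed_line_error_names_line_number(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t100\t200\tp\t1\t+\nchr1\tnotanint\t300\n")
        with pytest.raises(ValueError, match=":2:"):
            read_peaks(path, "bed6")

    @pytest.mark.parametrize("dialect", ["bed6", "narrowPeak"])
    def test_round_trip_preserves_peaks(self, tmp_path, rng, dialect):
        centres = sorted(rng.integers(1000, 100_000, size=30).tolist())
        original = _cistrome("F", centres)
        path = tmp_path / f"rt.{dialect}"
        write_peaks(original, path, dialect)
        back = read_peaks(path, dialect, factor="F")
        assert [(p.chrom, p.start, p.end, p.centre, p.name) for p in back.peaks] == \
               [(p.chrom, p.start, p.end, p.centre, p.name) for p in original.peaks]


class TestClustering:
    def test_within_radius_joins_cluster(self):
        clusters = cluster_peaks([_cistrome("A", [100]), _cistrome("B", [299])])
        assert len(clusters) == 1
        assert clusters[0].signature == {"A", "B"}

    def test_exact_250_gap_splits(self):
        # distance 250 is not "< 250": separate clusters
        clusters = cluster_peaks([_cistrome("A", [100]), _cistrome("B", [350])])
        assert len(clusters) == 2

    def test_greedy_index_convention_chain(self):
        # 100 and 300 share an index; 500 is 400 bp from index 100
        clusters = cluster_peaks([_cistrome("A", [100, 500]), _cistrome("B", [300])])
        centres = [sorted(p.centre for _, p in cl.members) for cl in clusters]
        assert centres == [[100, 300], [500]]

    def test_partition_covers_every_peak_once(self, rng):
        cistromes = [
            _cistrome(f, sorted(rng.integers(0, 50_000, size=60).tolist()))
            for f in "ABC"
        ]
        clusters = cluster_peaks(cistromes)
        n_members = sum(len(cl.members) for cl in clusters)
        assert n_members == sum(len(c) for c in cistromes)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(25):
            pooled = []
            for label in "AB":
                for c in rng.integers(100, 20_000, size=40):
                    pooled.append(("chr1", int(c), float(rng.integers(1, 100)), label))
            tracks = [
                Cistrome(label, [Peak("chr1", c - 50, c + 51, c, s)
                                 for _, c, s, lab in pooled if lab == label])
                for label in "AB"
            ]
            clusters = cluster_peaks(tracks, radius=250)
            got = sorted(sorted(p.centre for _, p in cl.members) for cl in clusters)
            expected = sorted(
                sorted(pooled[i][1] for i in grp)
                for grp in brute_force_clusters(pooled)
            )
            assert got == expected

    def test_insensitive_to_input_order(self, rng):
        cistromes = [
            _cistrome(f, sorted(rng.integers(0, 30_000, size=50).tolist()))
            for f in "ABC"
        ]
        ref = cluster_peaks(cistromes)
        shuffled = cluster_peaks(cistromes[::-1])
        key = lambda cls: [
            (cl.index_peak.centre, sorted(p.centre for _, p in cl.members))
            for cl in cls
        ]
        assert key(ref) == key(shuffled)

    def test_empty_input_is_empty_output(self):
        assert cluster_peaks([Cistrome("A", [])]) == []


class TestSignatures:
    def test_counts_by_exact_signature(self):
        clusters = cluster_peaks([
            _cistrome("A", [1000, 5000, 9000]),
            _cistrome("B", [5050, 9050]),
        ])
        assert occupancy_signature_counts(clusters) == {"A": 1, "A_B": 2}

    def test_counts_sum_to_cluster_count(self, rng):
        cistromes = [
            _cistrome(f, sorted(rng.integers(0, 100_000, size=80).tolist()))
            for f in "AB"
        ]
        clusters = cluster_peaks(cistromes)
        assert sum(occupancy_signature_counts(clusters).values()) == len(clusters)

    def test_signature_label_is_sorted(self):
        assert signature_label({"SPIB", "IRF4"}) == "IRF4_SPIB"


class TestDistanceProfile:
    def test_self_comparison_is_all_zero(self):
        c = _cistrome("A", [1000, 2000, 3000])
        prof = centre_distance_profile(c, c)
        assert (prof.distances == 0).all()
        assert prof.fraction_within_50 == 1.0

    def test_signed_offset_and_50bp_fraction(self):
        prof = centre_distance_profile(_cistrome("A", [1000]), _cistrome("B", [1060]))
        assert list(prof.distances) == [60]
        assert prof.fraction_within_50 == 0.0

    def test_jitter_gives_sqrt2_sd(self):
        # two independently jittered centres differ with sd sqrt(2) * 20
        from cofbal.synthetic import CistromeSimSpec, gen_cistromes

        spec = CistromeSimSpec(
            factors=("A", "B"), n_elements_per_factor=2000,
            sharing=np.array([[1.0, 1.0], [1.0, 1.0]]),
            centre_jitter_sd=20.0, seed=5,
        )
        cistromes, _ = gen_cistromes(spec)
        prof = centre_distance_profile(cistromes["A"], cistromes["B"])
        sd = prof.distances.std()
        assert abs(sd - np.sqrt(2) * 20) < 1.5


class TestGeneAssignment:
    def test_upstream_boundary_is_strict_5kb(self, small_genes):
        inside = _cistrome("F", [100_000 - 4999])
        outside = _cistrome("F", [100_000 - 5001])
        assert "g1" in assign_peaks_to_genes(inside, small_genes)
        assert "g1" not in assign_peaks_to_genes(outside, small_genes)

    def test_minus_strand_upstream_is_right_of_tss(self, small_genes):
        up = _cistrome("F", [219_999 + 3000])
        down = _cistrome("F", [219_999 + 5001])
        assert "g2" in assign_peaks_to_genes(up, small_genes)
        assert "g2" not in assign_peaks_to_genes(down, small_genes)

    def test_agrees_with_interval_oracle_on_random_genes(self, rng):
        from cofbal.synthetic import gen_gene_models

        genes = gen_gene_models(100, {"chr1": 10_000_000}, seed=3)
        centres = sorted(int(c) for c in rng.integers(0, 10_000_000, size=500))
        cistrome = _cistrome("F", centres)
        got = assign_peaks_to_genes(cistrome, genes, "upstream5kb_intragenic")
        for g in genes:
            if g.strand == "+":
                window_ok = lambda c: (g.tss - 5000 <= c < g.tss) or (g.body_start <= c < g.body_end)
            else:
                window_ok = lambda c: (g.tss < c <= g.tss + 5000) or (g.body_start <= c < g.body_end)
            expected = [c for c in centres if window_ok(c)]
            assert sorted(p.centre for p in got.get(g.gene_id, [])) == expected

    def test_tss_flank_mode_is_symmetric(self, small_genes):
        got = assign_peaks_to_genes(
            _cistrome("F", [100_000 - 2000, 100_000 + 2000, 100_000 + 2501]),
            small_genes, mode="tss_flank", flank=2000,
        )
        assert [p.centre for p in got["g1"]] == [98_000, 102_000]

    def test_unknown_mode_rejected(self, small_genes):
        with pytest.raises(ValueError, match="unknown mode"):
            assign_peaks_to_genes(_cistrome("F", [1000]), small_genes, mode="bogus")


class TestPromoterFraction:
    def test_all_at_tss_gives_one(self, small_genes):
        c = _cistrome("F", [g.tss for g in small_genes if g.chrom == "chr1"])
        assert promoter_fraction(c, small_genes) == 1.0

    def test_far_from_genes_gives_zero(self, small_genes):
        assert promoter_fraction(_cistrome("F", [5_000_000]), small_genes) == 0.0

    def test_recovers_planted_promoter_rate(self, rng):
        from cofbal.synthetic import gen_gene_models

        genes = gen_gene_models(200, {"chr1": 20_000_000}, seed=9)
        n, rate = 1000, 0.3
        at_promoter = rng.random(n) < rate
        centres = []
        for hit in at_promoter:
            if hit:
                g = genes[rng.integers(len(genes))]
                centres.append(int(g.tss + rng.integers(-2000, 2001)))
            else:
                centres.append(int(18_000_000 + rng.integers(0, 1_000_000)))
        frac = promoter_fraction(_cistrome("F", sorted(centres)), genes)
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(frac - at_promoter.mean()) < 3 * se


class TestMotifScanning:
    GENOME = {"chr1": "A" * 300}

    def _genome_with(self, insert, at=150):
        s = "ACGT" * 200
        return {"chr1": s[:at] + insert + s[at + len(insert):]}

    def test_ap1_degenerate_base_matches(self):
        genome = self._genome_with("TGAGTCA")
        counts = count_motif_matches(
            [Peak("chr1", 100, 200, 150)], genome,
            [MotifPattern("AP1", "TGASTCA", both_strands=False)], window=50,
        )
        assert counts.iloc[0]["AP1"] == 1

    def test_reverse_embedding_needs_both_strands(self):
        # reverse complement of the EICE instance GGAAGTGAAAC
        genome = self._genome_with("GTTTCACTTCC")
        region = [Peak("chr1", 100, 200, 150)]
        fwd = count_motif_matches(region, genome,
                                  [MotifPattern("EICE", "GGAARTGAAAC", both_strands=False)],
                                  window=50)
        both = count_motif_matches(region, genome,
                                   [MotifPattern("EICE", "GGAARTGAAAC", both_strands=True)],
                                   window=50)
        assert fwd.iloc[0]["EICE"] == 0
        assert both.iloc[0]["EICE"] >= 1

    def test_matches_regex_oracle_on_random_sequences(self, rng):
        patterns = [
            MotifPattern("EICE", "GGAARTGAAAC"),
            MotifPattern("AP1", "TGASTCA"),
            MotifPattern("ETS", "RGGAAR"),
        ]
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=201))
            genome = {"chr1": seq}
            counts = count_motif_matches(
                [Peak("chr1", 50, 150, 100)], genome, patterns, window=100
            )
            for pat in patterns:
                assert counts.iloc[0][pat.name] == regex_motif_count(seq, pat.iupac, True)

    def test_ets_within_eice_suppression(self):
        # the EICE consensus embeds an ETS core; suppression removes that hit
        genome = self._genome_with("GGAAGTGAAAC")
        region = [Peak("chr1", 100, 200, 150)]
        patterns = [
            MotifPattern("EICE", "GGAARTGAAAC", both_strands=False),
            MotifPattern("ETS", "RGGAAR", both_strands=False),
        ]
        free = count_motif_matches(region, genome, patterns, window=50)
        suppressed = count_motif_matches(
            region, genome, patterns, window=50, suppress_within={"ETS": "EICE"}
        )
        assert free.iloc[0]["EICE"] == 1
        assert suppressed.iloc[0]["ETS"] < free.iloc[0]["ETS"] or free.iloc[0]["ETS"] == 0

    def test_region_outside_contig_is_an_error(self):
        with pytest.raises(ValueError, match="outside contig"):
            count_motif_matches([Peak("chr1", 0, 60, 30)], self.GENOME,
                                [MotifPattern("AP1", "TGASTCA")], window=100)

    def test_indexed_fasta_path_gives_same_counts_as_dict(self, tmp_path):
        from cofbal.synthetic import gen_motif_sequences, write_fasta

        records, _ = gen_motif_sequences(
            [MotifPattern("AP1", "TGASTCA")], 5, 200, [(0, "AP1", 90, "+")], seed=6
        )
        path = tmp_path / "toy.fa"
        write_fasta(records, path)
        regions = [Peak(name, 0, 200, 100) for name, _ in records]
        patterns = [MotifPattern("AP1", "TGASTCA")]
        from_dict = count_motif_matches(regions, dict(records), patterns, window=80)
        from_fasta = count_motif_matches(regions, str(path), patterns, window=80)
        assert (from_dict.to_numpy() == from_fasta.to_numpy()).all()
        assert from_dict.iloc[0]["AP1"] >= 1

    def test_ambiguous_genome_base_is_mismatch(self):
        genome = {"chr1": "N" * 300}
        counts = count_motif_matches([Peak("chr1", 100, 200, 150)], genome,
                                     [MotifPattern("ANY", "NNNN")], window=20)
        assert counts.iloc[0]["ANY"] == 0
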