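"""Windows, fragments, discovery, exact-p scanning, positional enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from regennet import motif as mo


def _genome_one_contig(seq, gene="g1", tss=None, strand="+"):
    ann = pd.DataFrame([{"gene": gene, "contig": "chr1",
                         "tss": tss if tss is not None else len(seq) // 2,
                         "strand": strand}])
    return ann, {"chr1": seq}


class TestExtractWindows:
    def test_plus_strand_window_coordinates(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 200_000))
        ann, genome = _genome_one_contig(seq, tss=60_000)
        w = mo.extract_windows(ann, genome, halfwidth=50_000)["g1"]
        assert (w.start, w.end) == (10_000, 110_000)
        assert len(w.seq) == 100_000
        assert w.offset_of(0) == -50_000
        assert w.seq == seq[10_000:110_000]

    def test_clipping_at_contig_edge(self):
        seq = "A" * 100_000
        ann, genome = _genome_one_contig(seq, tss=10_000)
        w = mo.extract_windows(ann, genome, halfwidth=50_000)["g1"]
        assert (w.start, w.end) == (0, 60_000)
        assert w.offset_of(0) == -10_000
        assert w.offset_of(len(w.seq) - 1) == 49_999

    def test_minus_strand_reverse_complemented_with_negated_offsets(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        ann, genome = _genome_one_contig(seq, tss=500, strand="-")
        w = mo.extract_windows(ann, genome, halfwidth=100)["g1"]
        assert w.seq == mo.revcomp(seq[400:600])
        # the base at plus-strand offset +d sits at oriented offset -d
        plus = mo.extract_windows(
            *reversed(_genome_one_contig(seq, tss=500, strand="+")),
            halfwidth=100) if False else None
        i = 10
        plus_coord = w.end - 1 - i
        assert w.offset_of(i) == -(plus_coord - 500)

    def test_missing_contig_and_bad_tss_rejected(self):
        ann = pd.DataFrame([{"gene": "g", "contig": "nope", "tss": 5,
                             "strand": "+"}])
        with pytest.raises(KeyError, match="nope"):
            mo.extract_windows(ann, {"chr1": "ACGT"})
        ann2 = pd.DataFrame([{"gene": "g", "contig": "chr1", "tss": 99,
                              "strand": "+"}])
        with pytest.raises(ValueError, match="g"):
            mo.extract_windows(ann2, {"chr1": "ACGT"})


class TestFragmentAndLabel:
    def _windows(self, n_bp, gene="g1"):
        seq = "A" * n_bp
        ann, genome = _genome_one_contig(seq, gene=gene, tss=n_bp // 2)
        return mo.extract_windows(ann, genome, halfwidth=n_bp)

    def test_tiling_counts_and_remainder(self):
        frags = mo.fragment_and_label(self._windows(100_000), set())
        assert len(frags) == 1000
        frags = mo.fragment_and_label(self._windows(250), set())
        assert len(frags) == 2  # 50 bp remainder dropped

    def test_labels_follow_gene_membership(self):
        frags = mo.fragment_and_label(self._windows(300, "g1"), {"g1"})
        assert all(f.label == "target" for f in frags)
        frags = mo.fragment_and_label(self._windows(300, "g1"), {"other"})
        assert all(f.label == "control" for f in frags)

    def test_base_conservation(self):
        windows = self._windows(433)
        frags = mo.fragment_and_label(windows, set())
        total = sum(len(f.seq) for f in frags)
        assert total == (len(windows["g1"].seq) // 100) * 100

    def test_invalid_fragment_size(self):
        with pytest.raises(ValueError):
            mo.fragment_and_label({}, set(), fragment_size=0)


class TestBipartiteScan:
    def test_documented_example_hit(self):
        mm = mo.MotifModel(kind="bipartite", forward="CAAC", reverse="GATG",
                           spacer=(0, 0))
        hits = mo.scan({"s": "TTCAACGATGTT"}, mm)
        assert len(hits) == 1
        assert (hits.iloc[0]["start"], hits.iloc[0]["end"]) == (2, 10)
        assert hits.iloc[0]["matched"] == "CAACGATG"

    def test_poly_a_yields_nothing(self):
        mm = mo.MotifModel(kind="bipartite")
        assert mo.scan({"s": "A" * 200}, mm).empty

    def test_degenerate_halves_and_spacer_range(self):
        mm = mo.MotifModel(kind="bipartite", forward="CNNC", reverse="GNNG",
                           spacer=(0, 2))
        hits = mo.scan({"s": "CTTCAAGTAG"}, mm, both_strands=False)
        # CTTC (CNNC) + spacer 2 "AA" + GTAG (GNNG)
        assert ((hits["start"] == 0) & (hits["end"] == 10)).any()

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 500))
        mm = mo.MotifModel(kind="bipartite", forward="CAAC", reverse="GATG",
                           spacer=(0, 5))
        L = len(seq)
        fwd = mo.scan({"s": seq}, mm)
        rev = mo.scan({"s": mo.revcomp(seq)}, mm)
        assert ({(r.start, r.end) for r in fwd.itertuples()}
                == {(L - r.end, L - r.start) for r in rev.itertuples()})

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            mo.MotifModel(kind="bipartite", forward="CAXC")


class TestPwmScan:
    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5, 6])
    def test_exact_pvalues_match_enumeration(self, width):
        rng = np.random.default_rng(width)
        probs = rng.dirichlet(np.ones(4), size=width)
        bg = np.array([0.3, 0.2, 0.3, 0.2])
        m = mo.MotifModel(kind="pwm", probs=probs, background=bg)
        scores, sf = mo.exact_pwm_pvalues(m)
        lo = m.log_odds()
        word_probs: dict[float, float] = {}
        for word in itertools.product(range(4), repeat=width):
            s, p = 0.0, 1.0
            for k, b in enumerate(word):
                s = s + lo[k, b]
                p *= bg[b]
            word_probs[s] = word_probs.get(s, 0.0) + p
        brute = np.array(sorted(word_probs))
        brute_sf = np.cumsum([word_probs[s] for s in brute][::-1])[::-1]
        assert np.array_equal(brute, scores)
        assert np.allclose(brute_sf, sf, rtol=1e-12, atol=1e-15)

    def test_hits_filtered_by_alpha_and_sorted(self):
        probs = np.array([[0.97, 0.01, 0.01, 0.01]] * 4)
        m = mo.MotifModel(kind="pwm", probs=probs)
        hits = mo.scan({"s": "TTAAAATTTAAAAT"}, m, alpha=0.01,
                       both_strands=False)
        assert list(hits["start"]) == sorted(hits["start"])
        assert set(hits["matched"]) == {"AAAA"}
        assert (hits["p_value"] <= 0.01).all()

    def test_n_bases_never_match(self):
        probs = np.array([[0.97, 0.01, 0.01, 0.01]] * 4)
        m = mo.MotifModel(kind="pwm", probs=probs)
        hits = mo.scan({"s": "AANAA"}, m, alpha=1.0, both_strands=False)
        assert hits.empty  # every 4-mer window overlaps the N

    def test_meme_roundtrip(self, tmp_path):
        rng = np.random.default_rng(9)
        m = mo.MotifModel(kind="pwm", probs=rng.dirichlet(np.ones(4), 6),
                          background=np.array([0.2, 0.3, 0.2, 0.3]),
                          name="test_motif")
        path = tmp_path / "m.meme"
        m.to_meme(path)
        back = mo.MotifModel.from_meme(path)
        assert back.name == "test_motif"
        assert np.allclose(back.probs, m.probs, atol=1e-6)
        assert np.allclose(back.background, m.background, atol=1e-5)


class TestDiscovery:
    @staticmethod
    def _fragments(rng, n, plant_rate, word):
        out = []
        for _ in range(n):
            s = "".join(rng.choice(list("ACGT"), 100))
            if rng.random() < plant_rate:
                pos = int(rng.integers(0, 100 - len(word)))
                s = s[:pos] + word + s[pos + len(word):]
            out.append(s)
        return out

    def test_planted_word_recovered_within_hamming_one(self):
        word = "CAACGATG"
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = self._fragments(rng, 500, 0.4, word)
            c = self._fragments(rng, 500, 0.01, word)
            top = mo.discover_discriminative_motif(t, c, widths=[8],
                                                   top_n=1)[0]
            ham = sum(a != b for a, b in zip(top["consensus"], word))
            hits += ham <= 1
        assert hits >= 9

    def test_identical_sets_yield_no_significant_motif(self):
        rng = np.random.default_rng(2)
        frags = self._fragments(rng, 100, 0.0, "")
        res = mo.discover_discriminative_motif(frags, frags, widths=[6])
        assert all(not r["significant"] for r in res)
        assert min(r["p_corrected"] for r in res) == 1.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="target"):
            mo.discover_discriminative_motif([], ["ACGT"], widths=[2])
        with pytest.raises(ValueError, match="control"):
            mo.discover_discriminative_motif(["ACGT"], [], widths=[2])

    def test_pwm_extension_centers_on_seed(self):
        rng = np.random.default_rng(3)
        word = "CAACGATG"
        t = self._fragments(rng, 300, 0.8, word)
        c = self._fragments(rng, 300, 0.0, word)
        top = mo.discover_discriminative_motif(t, c, widths=[8], top_n=1)[0]
        pwm = top["pwm"]
        core = pwm.consensus()[2:-2]
        assert sum(a != b for a, b in zip(core, word)) <= 1


class TestPositionalEnrichment:
    def test_identical_multisets_give_unit_ratio(self):
        rng = np.random.default_rng(0)
        offs = rng.integers(-50_000, 50_000, 5000)
        curve = mo.positional_enrichment(offs, offs.copy())
        assert np.all(np.abs(curve.ratio - 1.0) < 1e-9)

    def test_planted_peak_found_at_statistical_resolution(self):
        # a Normal(0, 500 bp) target peak against uniform controls: the
        # ratio's argmax concentrates on the peak but its sampling sd is a
        # few hundred bp at 10,000 hits (see methods note)
        rng = np.random.default_rng(21)
        t = rng.normal(0, 500, 10_000)
        c = rng.uniform(-50_000, 50_000, 10_000)
        curve = mo.positional_enrichment(t, c)
        assert abs(curve.argmax_offset) <= 1500

    def test_empty_control_bins_stay_finite(self):
        t = np.zeros(100)
        c = np.full(100, 40_000.0)
        curve = mo.positional_enrichment(t, c)
        assert np.all(np.isfinite(curve.ratio))

    def test_scale_invariance_of_mean_normalization(self):
        rng = np.random.default_rng(7)
        t = rng.normal(0, 2000, 2000)
        c = rng.uniform(-50_000, 50_000, 2000)
        a = mo.positional_enrichment(t, c)
        b = mo.positional_enrichment(np.repeat(t, 3), np.repeat(c, 3))
        # tripling every hit leaves the normalized curves unchanged
        assert np.allclose(a.f_target, b.f_target)
        assert np.allclose(a.f_control, b.f_control)

    def test_empty_hit_sets_rejected(self):
        with pytest.raises(ValueError):
            mo.positional_enrichment([], [1, 2, 3])

    def test_bins_tile_window_and_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        curve = mo.positional_enrichment(rng.normal(0, 300, 500),
                                         rng.uniform(-5000, 5000, 500),
                                         halfwidth=5000)
        assert len(curve.bin_centers) == 1000
        assert curve.bin_centers[0] == -4995.0
        curve.to_tsv(tmp_path / "c.tsv")
        back = pd.read_csv(tmp_path / "c.tsv", sep="\t")
        assert len(back) == 1000
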