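"""Unit and oracle tests for primer panel design."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concatag.dna import AlphabetError, BAMHI_SITE, HINDIII_SITE, reverse_complement
from concatag.panel_design import (
    DEFAULT_ADAPTORS,
    DEFAULT_CONSTRAINTS,
    ChimericPrimerPair,
    DesignConstraints,
    GeneTarget,
    NoCandidatesError,
    PanelInfeasibleError,
    PrimerPanel,
    UniversalAdaptors,
    design_panel,
    enumerate_candidates,
    melting_temperature,
    validate_panel,
)

dna = st.text(alphabet="ACGT", min_size=8, max_size=30)


# ---------------------------------------------------------------------------
# independent nearest-neighbor Tm oracle (SantaLucia & Hicks 2004 table,
# Owczarzy 2008 divalent correction), hand-coded from the publications
# ---------------------------------------------------------------------------

_DH = {"AA": -7.6, "TT": -7.6, "AT": -7.2, "TA": -7.2, "CA": -8.5, "TG": -8.5,
       "GT": -8.4, "AC": -8.4, "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
       "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0}
_DS = {"AA": -21.3, "TT": -21.3, "AT": -20.4, "TA": -21.3, "CA": -22.7, "TG": -22.7,
       "GT": -22.4, "AC": -22.4, "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
       "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9}


def oracle_tm(seq: str, dnac1=200e-9, mon=0.05, mg=0.005) -> float:
    dh, ds = 0.2, -5.7
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += 2.2
            ds += 6.9
    for i in range(len(seq) - 1):
        dh += _DH[seq[i : i + 2]]
        ds += _DS[seq[i : i + 2]]
    tm = dh * 1000.0 / (ds + 1.987 * math.log(dnac1))  # Kelvin at 1 M Na+
    fgc = (seq.count("G") + seq.count("C")) / len(seq)
    a = 3.92e-5 * (0.843 - 0.352 * math.sqrt(mon) * math.log(mon))
    b = -9.11e-6
    c = 6.26e-5
    d = 1.42e-5 * (1.279 - 4.03e-3 * math.log(mon) - 8.03e-3 * math.log(mon) ** 2)
    e = -4.82e-4
    f = 5.25e-4
    g = 8.31e-5 * (0.486 - 0.258 * math.log(mon) + 5.25e-3 * math.log(mon) ** 3)
    lnmg = math.log(mg)
    inv = 1 / tm + a + b * lnmg + fgc * (c + d * lnmg) + (
        1 / (2 * (len(seq) - 1))
    ) * (e + f * lnmg + g * lnmg ** 2)
    return 1 / inv - 273.15


class TestMeltingTemperature:
    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            melting_temperature("")

    def test_short_sequence_errors(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG")  # 7 nt < 8

    def test_non_acgt_errors(self):
        with pytest.raises(AlphabetError):
            melting_temperature("ACGTNACGTACG")

    def test_matches_hand_computed_nn_oracle(self):
        seq = "AGCGTAGCTGGGATCCAGCA"
        assert melting_temperature(seq) == pytest.approx(oracle_tm(seq), abs=0.3)

    def test_oracle_agreement_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(12, 26))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert melting_temperature(seq) == pytest.approx(oracle_tm(seq), abs=0.3)

    @given(dna)
    @settings(max_examples=60, deadline=None)
    def test_strand_symmetry(self, seq):
        assert melting_temperature(seq) == pytest.approx(
            melting_temperature(reverse_complement(seq)), abs=1e-6
        )

    def test_deterministic(self):
        assert melting_temperature("ACGTACGTACGTACGT") == melting_temperature(
            "ACGTACGTACGTACGT"
        )

    def test_gc_append_monotonic(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            base = "".join(rng.choice(list("ACGT"), size=16))
            assert melting_temperature(base + "GC") >= melting_temperature(base)


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------


def brute_force_candidates(gene: GeneTarget, adaptors=DEFAULT_ADAPTORS,
                           constraints=DEFAULT_CONSTRAINTS):
    """Exhaustive enumeration of (start, end, fwd_len, rev_len) by direct
    constraint checking on the assembled product."""
    seq = gene.sequence
    lo, hi = constraints.specific_len_range
    amp_min, amp_max = constraints.amplicon_window
    tag_min, tag_max = constraints.tag_len_range
    discard = adaptors.left_discard + adaptors.right_discard
    found = []
    for start in range(len(seq)):
        for end in range(start + 1, len(seq) + 1):
            product = (adaptors.forward_tag + seq[start:end]
                       + reverse_complement(adaptors.reverse_tag))
            if not (amp_min <= len(product) <= amp_max):
                continue
            if not (tag_min <= len(product) - discard <= tag_max):
                continue
            if [i for i in range(len(product)) if product.startswith(BAMHI_SITE, i)] != [
                adaptors.bamhi_offset
            ]:
                continue
            if [i for i in range(len(product)) if product.startswith(HINDIII_SITE, i)] != [
                len(product) - adaptors.hindiii_offset - 6
            ]:
                continue
            for fwd_len in range(lo, hi + 1):
                for rev_len in range(lo, hi + 1):
                    if fwd_len + rev_len <= end - start:
                        found.append((start, end, fwd_len, rev_len))
    return sorted(found)


class TestEnumerateCandidates:
    def test_too_short_gene_errors_with_diagnostic(self):
        gene = GeneTarget("short", "ACGT" * 10)  # 40 bp < minimal 43 bp span
        with pytest.raises(NoCandidatesError, match="short"):
            enumerate_candidates(gene)

    def test_matches_brute_force_oracle(self, toy_gene):
        gene = GeneTarget("toy", toy_gene)
        got = enumerate_candidates(gene)
        got_keys = sorted(
            (p.amplicon_interval[0], p.amplicon_interval[1],
             len(p.fwd_specific), len(p.rev_specific))
            for p in got
        )
        assert got_keys == brute_force_candidates(gene)

    def test_site_blocked_gene_returns_empty(self):
        gene = GeneTarget("blocked", (BAMHI_SITE + "A") * 8)  # 56 bp, site everywhere
        assert enumerate_candidates(gene) == []

    def test_sorted_by_start_then_length(self, toy_gene):
        got = enumerate_candidates(GeneTarget("toy", toy_gene))
        keys = [(p.amplicon_interval[0], p.amplicon_len) for p in got]
        assert keys == sorted(keys)

    def test_every_candidate_satisfies_invariants(self, toy_gene):
        gene = GeneTarget("toy", toy_gene)
        for p in enumerate_candidates(gene):
            assert 78 <= p.amplicon_len <= 92
            product = p.amplicon_sequence(gene)
            assert len(product) == p.amplicon_len
            assert product.count(BAMHI_SITE) == 1
            assert product.count(HINDIII_SITE) == 1
            assert 60 <= p.amplicon_len - 20 <= 70
            assert 16 <= len(p.fwd_specific) <= 20
            assert 16 <= len(p.rev_specific) <= 20


# ---------------------------------------------------------------------------
# panel design
# ---------------------------------------------------------------------------


def _toy_genes(lengths, seed=9):
    rng = np.random.default_rng(seed)
    genes = []
    for i, n in enumerate(lengths):
        while True:
            seq = "".join(rng.choice(list("ACGT"), size=n))
            if BAMHI_SITE not in seq and HINDIII_SITE not in seq:
                break
        genes.append(GeneTarget(f"g{i}", seq, is_control=(i == 0)))
    return genes


def brute_force_panel(genes, adaptors=DEFAULT_ADAPTORS, constraints=DEFAULT_CONSTRAINTS):
    """Exhaustive cross-product minimization with the documented tie-break."""
    cands = [enumerate_candidates(g, adaptors, constraints) for g in genes]
    order = sorted(range(len(genes)), key=lambda i: genes[i].gene_id)
    best_key, best = None, None
    for combo in itertools.product(*cands):
        tms = [t for p in combo for t in (p.tm_fwd, p.tm_rev)]
        spread = max(tms) - min(tms)
        chosen = [combo[i] for i in order]
        key = (
            round(spread, 9),
            sum(abs(p.amplicon_len - constraints.amplicon_center) for p in chosen),
            tuple(p.amplicon_interval[0] for p in chosen),
            tuple((p.amplicon_len, len(p.fwd_specific), len(p.rev_specific)) for p in chosen),
        )
        if best_key is None or key < best_key:
            best_key, best = key, combo
    return best_key, {p.gene_id: p for p in best}


class TestDesignPanel:
    def test_requires_exactly_one_control(self):
        genes = _toy_genes([60, 60])
        no_control = [GeneTarget(g.gene_id, g.sequence, is_control=False) for g in genes]
        with pytest.raises(ValueError, match="control"):
            design_panel(no_control)

    def test_matches_brute_force_on_three_genes(self):
        genes = _toy_genes([43, 43, 44], seed=17)
        panel = design_panel(genes)
        oracle_key, oracle = brute_force_panel(genes)
        got = {p.gene_id: p for p in panel.pairs}
        assert set(got) == set(oracle)
        for gid in oracle:
            assert got[gid].amplicon_interval == oracle[gid].amplicon_interval
            assert got[gid].fwd_specific == oracle[gid].fwd_specific
            assert got[gid].rev_specific == oracle[gid].rev_specific
        assert panel.max_pairwise_dtm == pytest.approx(oracle_key[0], abs=1e-9)

    def test_matches_brute_force_on_four_genes(self):
        genes = _toy_genes([43, 43, 43, 44], seed=23)
        panel = design_panel(genes)
        _, oracle = brute_force_panel(genes)
        got = {p.gene_id: p for p in panel.pairs}
        for gid in oracle:
            assert got[gid].amplicon_interval == oracle[gid].amplicon_interval

    def test_infeasible_tm_gap_raises_naming_genes(self):
        at_rich = GeneTarget("coldgene", "AT" * 25, is_control=True)
        gc_rich = GeneTarget("hotgene", "GC" * 25)
        with pytest.raises(PanelInfeasibleError, match="coldgene|hotgene"):
            design_panel([at_rich, gc_rich])

    def test_packaged_panel_meets_protocol_constraints(self, panel20):
        # max pairwise dTm <= 5 C and every product within 85 +/- 7 bp
        assert panel20.max_pairwise_dtm <= 5.0
        for p in panel20.pairs:
            assert 78 <= p.amplicon_len <= 92

    def test_one_pair_per_gene(self, panel20, genes20):
        assert sorted(p.gene_id for p in panel20.pairs) == sorted(
            g.gene_id for g in genes20
        )

    def test_deterministic(self):
        genes = _toy_genes([43, 43, 44], seed=17)
        p1 = design_panel(genes)
        p2 = design_panel(genes)
        assert [p.fwd_specific for p in p1.pairs] == [p.fwd_specific for p in p2.pairs]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


class TestValidatePanel:
    def test_passing_panel_has_no_violations(self, panel20, genes20):
        report = validate_panel(panel20, genes20)
        assert report.passed
        assert report.violations == []
        assert len(report.per_pair) == 20

    def test_out_of_window_amplicon_flagged(self, panel20, genes20):
        import dataclasses

        bad_pair = dataclasses.replace(panel20.pairs[0], amplicon_len=95)
        panel = PrimerPanel(pairs=(bad_pair,) + panel20.pairs[1:], adaptors=panel20.adaptors)
        report = validate_panel(panel, genes20)
        assert any("95" in v and "length" in v for v in report.violations)

    def test_duplicate_tags_warned(self):
        genes = _toy_genes([60], seed=41)
        gene_a = genes[0]
        gene_b = GeneTarget("g_dup", gene_a.sequence)  # identical sequence
        pair_a = enumerate_candidates(gene_a)[0]
        import dataclasses

        pair_b = dataclasses.replace(pair_a, gene_id="g_dup")
        panel = PrimerPanel(pairs=(pair_a, pair_b), adaptors=DEFAULT_ADAPTORS)
        report = validate_panel(panel, [gene_a, gene_b])
        assert any("identical tag" in w for w in report.warnings)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


class TestTypes:
    def test_gene_target_rejects_ambiguity_codes(self):
        with pytest.raises(AlphabetError):
            GeneTarget("g", "ACGTN" * 20)

    def test_adaptor_geometry_enforced(self):
        with pytest.raises(ValueError, match="18 nt"):
            UniversalAdaptors("ACTGCGTACGGGATCC", "GCATACGTCGAAGCTTCAG")
        with pytest.raises(ValueError, match="exactly one"):
            UniversalAdaptors("GGATCCACGTGGATCCAT", "GCATACGTCGAAGCTTCAG")
        with pytest.raises(ValueError, match="must not contain"):
            UniversalAdaptors("AAGCTTACGAGGATCCAT", "GCATACGTCGAAGCTTCAG")

    def test_default_adaptors_valid(self):
        assert len(DEFAULT_ADAPTORS.forward_tag) == 18
        assert len(DEFAULT_ADAPTORS.reverse_tag) == 19
        assert DEFAULT_ADAPTORS.forward_tag.count(BAMHI_SITE) == 1
        assert DEFAULT_ADAPTORS.reverse_tag.count(HINDIII_SITE) == 1

    def test_constraints_reject_bad_bounds(self):
        with pytest.raises(ValueError):
            DesignConstraints(specific_len_range=(20, 16))
        with pytest.raises(ValueError):
            DesignConstraints(max_pairwise_dtm=-1)

    def test_panel_rejects_duplicate_genes(self, panel20):
        with pytest.raises(ValueError, match="duplicate"):
            PrimerPanel(pairs=(panel20.pairs[0], panel20.pairs[0]), adaptors=panel20.adaptors)


class TestRandomizedPanelProperty:
    def test_amplicon_lengths_on_random_gene_sets(self):
        """Designed amplicon lengths stay in [78, 92] over random gene sets."""
        from concatag import datasets

        for seed in (101, 202):
            genes = datasets.synthetic_gene_targets(
                gene_ids=("a", "b", "c", "ctrl"), control="ctrl", seed=seed
            )
            panel = design_panel(genes)
            for p in panel.pairs:
                assert 78 <= p.amplicon_len <= 92
            assert panel.max_pairwise_dtm <= 5.0
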