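"""miRNA target scoring: penalty table, window search, DE join."""

import numpy as np
import pandas as pd
import pytest

from coldsrna import targets
from coldsrna.simulate import reverse_complement


def rc_rna(seq: str) -> str:
    return reverse_complement(seq).replace("T", "U")


MIRNA = "UGGAGCUCCCUUCAUUCCAAU"  # 21 nt


def site_with(mirna: str, changes: dict[int, str]) -> str:
    """Perfect site with substitutions at given miRNA positions (1-based).

    miRNA position p pairs with site index len - p (site written 5'->3').
    """
    site = list(rc_rna(mirna))
    for pos, base in changes.items():
        site[len(mirna) - pos] = base
    return "".join(site)


def wobble_partner(base: str) -> str:
    # G:U wobble: miRNA G faces site U, miRNA U faces site G
    return {"G": "U", "U": "G"}[base]


def mismatch_partner(mirna_base: str, site_base: str) -> str:
    for b in "ACGU":
        if b != site_base and not (
            (mirna_base, b) in (("G", "U"), ("U", "G"))
        ) and {"A": "U", "U": "A", "G": "C", "C": "G"}[mirna_base] != b:
            return b
    raise AssertionError


class TestScoreDuplex:
    def test_perfect_reverse_complement_scores_zero(self):
        score, alignment = targets.score_duplex(MIRNA, rc_rna(MIRNA))
        assert score == 0.0
        assert set(alignment[1]) == {"|"}

    def test_wobble_outside_seed_costs_half(self):
        pos = 15
        assert MIRNA[pos - 1] in "GU"
        site = site_with(MIRNA, {pos: wobble_partner(MIRNA[pos - 1])})
        assert targets.score_duplex(MIRNA, site)[0] == 0.5

    def test_wobble_in_seed_costs_one(self):
        pos = 5
        assert MIRNA[pos - 1] in "GU"
        site = site_with(MIRNA, {pos: wobble_partner(MIRNA[pos - 1])})
        assert targets.score_duplex(MIRNA, site)[0] == 1.0

    def test_cutoff_boundary_cases(self):
        # mismatch at seed position 3 (2.0) + wobble at position 21 (0.5)
        perfect = rc_rna(MIRNA)
        p3 = mismatch_partner(MIRNA[2], perfect[len(MIRNA) - 3])
        assert MIRNA[20] in "GU"
        site = site_with(MIRNA, {3: p3, 21: wobble_partner(MIRNA[20])})
        assert targets.score_duplex(MIRNA, site)[0] == pytest.approx(2.5)
        # two seed mismatches -> 4.0, over the stringent cutoff
        p4 = mismatch_partner(MIRNA[3], perfect[len(MIRNA) - 4])
        site2 = site_with(MIRNA, {3: p3, 4: p4})
        assert targets.score_duplex(MIRNA, site2)[0] == pytest.approx(4.0)

    def test_t_and_u_equivalent(self):
        dna = MIRNA.replace("U", "T")
        assert targets.score_duplex(dna, rc_rna(MIRNA))[0] == 0.0

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            targets.score_duplex("ACGX" * 5, "ACGU" * 5)

    def test_seed_weighting_breaks_reverse_complement_symmetry(self):
        """Swapping the roles of the two strands moves a defect between the
        seed and the tail, so the expectation changes even though the set
        of paired bases does not."""
        pos = 15  # non-seed here; becomes seed position 7 with roles swapped
        assert MIRNA[pos - 1] in "GU"
        site = site_with(MIRNA, {pos: wobble_partner(MIRNA[pos - 1])})
        forward = targets.score_duplex(MIRNA, site)[0]
        swapped = targets.score_duplex(site, MIRNA)[0]
        assert forward == 0.5
        assert swapped != forward


def brute_force_hits(mirnas, transcripts, cutoff):
    """Independent all-windows scorer with the same overlap reduction."""
    out = []
    for mid, m in mirnas.items():
        m = m.upper().replace("T", "U")
        for tid, t in transcripts.items():
            t = t.upper().replace("T", "U")
            wins = []
            for s in range(len(t) - len(m) + 1):
                score = targets.score_duplex(m, t[s:s + len(m)])[0]
                if score <= cutoff:
                    wins.append((s, score))
            chosen = []
            for s, score in sorted(wins, key=lambda w: (w[1], w[0])):
                if all(abs(s - c[0]) >= len(m) for c in chosen):
                    chosen.append((s, score))
            out.extend((mid, tid, s, score) for s, score in sorted(chosen))
    return sorted(out)


class TestFindTargets:
    def test_planted_exact_site_found_once(self):
        rng = np.random.default_rng(1)
        t = "".join(rng.choice(list("ACGU"), size=300))
        t = t[:100] + rc_rna(MIRNA) + t[100 + 21:]
        hits = targets.find_targets({"m": MIRNA}, {"t": t})
        exact = [h for h in hits if h.expectation == 0.0]
        assert len(exact) == 1
        assert exact[0].target_start == 100

    def test_equals_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        mirnas = {f"m{i}": "".join(rng.choice(list("ACGU"), size=21))
                  for i in range(3)}
        transcripts = {f"t{i}": "".join(rng.choice(list("ACGU"), size=500))
                       for i in range(3)}
        # loose cutoff so both scorers actually return windows
        hits = targets.find_targets(mirnas, transcripts, cutoff=14.0)
        ours = sorted((h.mirna, h.transcript, h.target_start, h.expectation)
                      for h in hits)
        assert ours == brute_force_hits(mirnas, transcripts, 14.0)

    def test_lowering_cutoff_never_adds_hits(self):
        rng = np.random.default_rng(8)
        mirnas = {"m": "".join(rng.choice(list("ACGU"), size=21))}
        transcripts = {"t": "".join(rng.choice(list("ACGU"), size=400))}
        loose = {(h.mirna, h.transcript, h.target_start)
                 for h in targets.find_targets(mirnas, transcripts, cutoff=15.0)}
        tight = {(h.mirna, h.transcript, h.target_start)
                 for h in targets.find_targets(mirnas, transcripts, cutoff=10.0)}
        assert tight <= loose

    def test_upe_filter_removes_inaccessible_sites(self):
        t = "AAAA" + rc_rna(MIRNA) + "AAAA"
        upe = pd.DataFrame([{"mirna": "m", "transcript": "t", "position": 4,
                             "upe": 30.0}])
        kept = targets.find_targets({"m": MIRNA}, {"t": t}, upe_table=upe,
                                    upe_max=25.0)
        assert kept == []
        kept = targets.find_targets({"m": MIRNA}, {"t": t}, upe_table=upe,
                                    upe_max=35.0)
        assert len(kept) == 1 and kept[0].upe == 30.0

    def test_short_transcript_yields_no_hits(self):
        assert targets.find_targets({"m": MIRNA}, {"t": "ACGU"}) == []

    def test_cleavage_vs_translation_flag(self):
        perfect = rc_rna(MIRNA)
        hit = targets.find_targets({"m": MIRNA}, {"t": perfect})[0]
        assert hit.inhibition == "cleavage"
        site = site_with(MIRNA, {10: mismatch_partner(
            MIRNA[9], perfect[len(MIRNA) - 10])})
        hits = targets.find_targets({"m": MIRNA}, {"t": site}, cutoff=3.0)
        assert hits and hits[0].inhibition == "translation"


class TestJoinTargetsToDe:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["feature", "time", "base_mean",
                                           "log2fc", "p", "p_adj", "status"])

    def test_no_de_mirna_gives_empty_table(self):
        hits = pd.DataFrame([{"mirna": "m1", "transcript": "g1"}])
        de_m = self._de([("m1", "3h", 50, 0.1, 0.5, 0.9, "unchanged")])
        out = targets.join_targets_to_de(hits, de_m, self._de([]))
        assert out.empty

    def test_row_per_target_per_time_point(self):
        hits = pd.DataFrame([{"mirna": "m1", "transcript": "g1"},
                             {"mirna": "m1", "transcript": "g2"}])
        de_m = self._de([("m1", "3h", 50, 2.0, 1e-4, 1e-3, "up"),
                         ("m1", "2d", 50, 2.0, 1e-4, 1e-3, "up")])
        de_g = self._de([("g1", "3h", 80, -1.5, 1e-3, 1e-2, "down"),
                         ("g1", "2d", 80, 0.0, 0.9, 0.95, "unchanged"),
                         ("g2", "3h", 2, 0.0, 1.0, 1.0, "undetected"),
                         ("g2", "2d", 2, 0.0, 1.0, 1.0, "undetected")])
        out = targets.join_targets_to_de(hits, de_m, de_g)
        assert len(out) == 4
        row = out[(out["transcript"] == "g1") & (out["time"] == "3h")].iloc[0]
        assert row["target_status"] == "down" and row["mirna_status"] == "up"

    def test_planted_pairs_all_present(self, small_catalog, small_counts,
                                       small_config):
        from coldsrna import diffexpr
        catalog, sequences = small_catalog
        srna, mrna, truth = small_counts
        mirnas = {f.id: sequences[f.id] for f in catalog.by_class("miRNA")}
        transcripts = {gid: sequences[gid] for gid in catalog.planted_sites}
        hits = targets.hits_to_frame(targets.find_targets(mirnas, transcripts))
        de_s = diffexpr.run_de(srna, small_config.samples())
        de_m = diffexpr.run_de(mrna, small_config.samples())
        joined = targets.join_targets_to_de(
            hits, de_s[de_s["feature"].isin(mirnas)], de_m)
        joined_pairs = set(zip(joined["mirna"], joined["transcript"]))
        de_mirnas = set(de_s.loc[de_s["status"].isin(["up", "down"]), "feature"])
        for mid, gid, _cat in truth.planted_target_pairs:
            if mid in de_mirnas:  # planted pairs of recovered DE miRNAs
                assert (mid, gid) in joined_pairs
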