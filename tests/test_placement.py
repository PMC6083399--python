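"""In-silico PCR placement: oracle equivalence, symmetry, failure modes."""

import numpy as np
import pytest

from qtlatlas import (
    InputError,
    ParameterError,
    PlacementParams,
    PrimerPair,
    find_primer_hits,
    place_markers,
    reverse_complement,
)
from qtlatlas.synthetic import generate_genome, plant_markers

from oracles import naive_primer_hits


def _pairs_from_frame(df):
    return [
        PrimerPair(r.marker, r.fwd, r.rev, int(r.expected_size))
        for r in df.itertuples(index=False)
    ]


def _as_tuples(hits):
    return sorted(
        (h.chrom, h.start, h.end, h.orientation, h.fwd_mismatches, h.rev_mismatches)
        for h in hits
    )


@pytest.fixture(scope="module")
def small_genome():
    return generate_genome(2, [4000, 3000], gc=0.45, seed=11, names=["A01", "A02"])


@pytest.fixture(scope="module")
def small_markers(small_genome):
    df, positions = plant_markers(
        small_genome, 6, primer_len=20, amplicon_range=(150, 400), seed=5
    )
    return df, positions


def _mutate(seq, pos, rng):
    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
    return seq[:pos] + alt + seq[pos + 1 :]


class TestFindPrimerHits:
    def test_planted_markers_recovered_exactly(self, small_genome, small_markers):
        df, positions = small_markers
        params = PlacementParams(max_mismatches=0)
        for pair in _pairs_from_frame(df):
            hits = find_primer_hits(small_genome, pair, params)
            chrom, start, end, _ = positions[pair.name]
            assert [(h.chrom, h.start, h.end, h.orientation) for h in hits] == [
                (chrom, start, end, "plus")
            ]
            assert hits[0].fwd_mismatches == 0 and hits[0].rev_mismatches == 0

    def test_matches_naive_sliding_window_oracle(self, small_genome, small_markers):
        """Hit sets equal an exhaustive per-offset scan, including primers
        carrying internal mismatches against their source site."""
        df, _ = small_markers
        rng = np.random.default_rng(3)
        params = PlacementParams(max_mismatches=1)
        checked_nonempty = 0
        for pair in _pairs_from_frame(df):
            # also perturb one internal base of the forward primer
            mutated = PrimerPair(
                pair.name + "_mut",
                _mutate(pair.fwd, int(rng.integers(2, len(pair.fwd) - 4)), rng),
                pair.rev,
                pair.expected_size,
            )
            for p in (pair, mutated):
                bounds = (len(p.fwd) + len(p.rev), 2000)
                got = _as_tuples(
                    find_primer_hits(small_genome, p, params, amplicon_bounds=bounds)
                )
                expected = naive_primer_hits(
                    small_genome, p.fwd, p.rev, 1, 3, bounds
                )
                assert got == expected
                checked_nonempty += bool(expected)
        assert checked_nonempty >= 6  # the comparison saw real hits

    def test_random_primers_against_random_genome_match_oracle(self):
        """Unplanted random primer pairs: implementation and brute force
        agree on the (almost always empty) hit sets too."""
        genome = generate_genome(1, [2000], gc=0.5, seed=9, names=["A01"])
        rng = np.random.default_rng(17)
        bases = "ACGT"
        params = PlacementParams(max_mismatches=1)
        for i in range(10):
            fwd = "".join(rng.choice(list(bases), 14))
            rev = "".join(rng.choice(list(bases), 14))
            p = PrimerPair(f"r{i}", fwd, rev)
            bounds = (28, 2000)
            got = _as_tuples(find_primer_hits(genome, p, params, amplicon_bounds=bounds))
            assert got == naive_primer_hits(genome, fwd, rev, 1, 3, bounds)

    def test_strand_symmetry(self, small_genome, small_markers):
        """On the reverse-complemented genome every hit reappears with the
        orientation flipped and coordinates mirrored."""
        df, _ = small_markers
        flipped = {c: reverse_complement(s) for c, s in small_genome.items()}
        params = PlacementParams(max_mismatches=1)
        for pair in _pairs_from_frame(df):
            fw = find_primer_hits(small_genome, pair, params)
            bw = find_primer_hits(flipped, pair, params)
            mirrored = sorted(
                (
                    h.chrom,
                    len(small_genome[h.chrom]) - h.end,
                    len(small_genome[h.chrom]) - h.start,
                    {"plus": "minus", "minus": "plus"}[h.orientation],
                    h.fwd_mismatches,
                    h.rev_mismatches,
                )
                for h in fw
            )
            assert _as_tuples(bw) == mirrored

    def test_hit_set_monotone_in_mismatch_allowance(self, small_genome, small_markers):
        df, _ = small_markers
        pair = _pairs_from_frame(df)[0]
        mutated = PrimerPair(pair.name, _mutate(pair.fwd, 5, None), pair.rev)
        previous = set()
        for k in (0, 1, 2):
            hits = {
                (h.chrom, h.start, h.end, h.orientation)
                for h in find_primer_hits(
                    small_genome, mutated, PlacementParams(max_mismatches=k),
                    amplicon_bounds=(40, 2000),
                )
            }
            assert previous <= hits
            previous = hits

    def test_amplicon_never_exceeds_chromosome(self, small_genome, small_markers):
        df, _ = small_markers
        for pair in _pairs_from_frame(df):
            for h in find_primer_hits(small_genome, pair, PlacementParams(2)):
                assert 0 <= h.start < h.end <= len(small_genome[h.chrom])

    def test_expected_size_narrows_bounds(self, small_genome, small_markers):
        """With expected_size present the window is +/-20%, so a declared
        size far from the planted amplicon length kills the hit."""
        df, positions = small_markers
        pair = _pairs_from_frame(df)[0]
        chrom, start, end, _ = positions[pair.name]
        true_len = end - start
        assert find_primer_hits(small_genome, pair, PlacementParams(0))
        wrong = PrimerPair(pair.name, pair.fwd, pair.rev, expected_size=true_len * 3)
        assert find_primer_hits(small_genome, wrong, PlacementParams(0)) == []

    def test_anchor_longer_than_primer_rejected(self, small_genome):
        p = PrimerPair("x", "ACGTACGTACGT", "ACGTACGTACGT")
        with pytest.raises(ParameterError):
            find_primer_hits(small_genome, p, PlacementParams(anchor_3prime=13))

    def test_empty_genome_gives_empty_hits(self):
        p = PrimerPair("x", "ACGTACGTACGT", "ACGTACGTACGT")
        assert find_primer_hits({}, p) == []

    def test_primer_validation(self):
        with pytest.raises(InputError):
            PrimerPair("short", "ACGTACGT", "ACGTACGTACGT")
        with pytest.raises(InputError):
            PrimerPair("iupac", "ACGTACGTACGR", "ACGTACGTACGT")


class TestPlaceMarkers:
    def test_all_planted_sites_unique(self, small_genome, small_markers):
        df, _ = small_markers
        result = place_markers(
            small_genome, _pairs_from_frame(df), PlacementParams(max_mismatches=0)
        )
        assert set(result.statuses.values()) == {"unique"}
        assert result.diagnostics().empty

    def test_duplicated_site_flagged_ambiguous(self, small_markers):
        """A marker whose amplicon is copied onto a second chromosome gets
        two hits, is labelled ambiguous and drops out of `unique`."""
        df, positions = small_markers
        pair = _pairs_from_frame(df)[0]
        genome = generate_genome(2, [4000, 3000], gc=0.45, seed=11, names=["A01", "A02"])
        chrom, start, end, _ = positions[pair.name]
        site = genome[chrom][start:end]
        genome["A02"] = site + genome["A02"][len(site):]
        result = place_markers(genome, [pair], PlacementParams(max_mismatches=0))
        assert result.statuses[pair.name] == "ambiguous"
        assert pair.name not in result.unique
        assert result.diagnostics().iloc[0]["n_hits"] == 2

    def test_shuffled_genome_leaves_markers_unplaced(self, small_genome, small_markers):
        """Negative control: on a base-composition-preserving shuffle of the
        genome, at least 95% of planted markers find no locus at k=0."""
        df, _ = small_markers
        rng = np.random.default_rng(23)
        shuffled = {
            c: "".join(rng.permutation(list(s))) for c, s in small_genome.items()
        }
        result = place_markers(
            shuffled, _pairs_from_frame(df), PlacementParams(max_mismatches=0)
        )
        frac_unplaced = result.counts()["unplaced"] / len(df)
        assert frac_unplaced >= 0.95

    def test_duplicate_marker_names_rejected(self, small_genome):
        p = PrimerPair("m", "ACGTACGTACGT", "ACGTACGTACGT")
        with pytest.raises(InputError, match="duplicate"):
            place_markers(small_genome, [p, p])
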