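import numpy as np
import pytest

from kdacsel.interactions import (
    ArgumentError,
    FrequencyTable,
    InteractionCriteria,
    InteractionRecord,
    PairingError,
    aggregate_frequencies,
    apply_low_frequency_filter,
    compute_occupancy,
    detect_contact,
    detect_hbond,
    detect_ionic,
    is_catalytic_frame,
    min_interatomic_distance,
    scan_interactions,
)
from kdacsel.peptides import PeptideSequence
from kdacsel.synthetic import markov_chain

from conftest import build_trajectory, frame_residues, random_complex
from oracles import (
    contact_bruteforce,
    hbond_backbone_bruteforce,
    hbond_sidechain_bruteforce,
    ionic_bruteforce,
    min_distance_bruteforce,
)

CRIT = InteractionCriteria()


class TestMinDistance:
    def test_single_pair(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[0.0, 0.0, 0.25]])
        assert min_interatomic_distance(a, b) == pytest.approx(0.25)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, (10, 3))
        b = rng.uniform(0, 1, (10, 3))
        assert min_interatomic_distance(a, b) == pytest.approx(
            min_distance_bruteforce(a, b)
        )

    def test_identical_sets_give_zero(self):
        a = np.random.default_rng(2).uniform(0, 1, (5, 3))
        assert min_interatomic_distance(a, a) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ArgumentError):
            min_interatomic_distance(np.empty((0, 3)), np.ones((1, 3)))


class TestDetectors:
    @pytest.mark.parametrize("dz,expected", [(0.29, True), (0.31, False)])
    def test_contact_cutoff(self, dz, expected):
        traj = build_trajectory(
            [("A", 10, "LEU", "CA"), ("B", 4, "TRP", "CB")],
            [[[0, 0, 0], [0, 0, dz]]],
        )
        assert detect_contact(traj.frames[0], ("A", 10, "LEU"), 1, CRIT) is expected

    @pytest.mark.parametrize("d,expected", [(0.20, True), (0.26, False)])
    def test_ionic_cutoff(self, d, expected):
        # enzyme Arg guanidinium H vs substrate Glu carboxylate O
        traj = build_trajectory(
            [
                ("A", 1, "ARG", "NH1"), ("A", 1, "ARG", "HH11"),
                ("B", 4, "GLU", "OE1"),
            ],
            [[[0, 0.1, 0], [0, 0, 0], [0, 0, d]]],
        )
        assert detect_ionic(traj.frames[0], ("A", 1, "ARG"), ("B", 4, "GLU"),
                            CRIT) is expected

    def test_ionic_needs_charged_pair(self):
        traj = build_trajectory(
            [("A", 1, "LEU", "CA"), ("B", 4, "TRP", "CB")],
            [[[0, 0, 0], [0, 0, 0.2]]],
        )
        with pytest.raises(PairingError):
            detect_ionic(traj.frames[0], ("A", 1, "LEU"), ("B", 4, "TRP"), CRIT)

    @pytest.mark.parametrize(
        "acceptor,expected",
        [
            ([0.29, 0, 0], True),    # collinear at 0.29 nm
            ([0.40, 0, 0], False),   # distance fail
        ],
    )
    def test_hbond_distance(self, acceptor, expected):
        traj = build_trajectory(
            [
                ("A", 3, "SER", "OG"), ("A", 3, "SER", "HG"),
                ("B", 4, "GLU", "OE1"),
            ],
            [[[0, 0, 0], [0.1, 0, 0], acceptor]],
        )
        got = detect_hbond(traj.frames[0], ("A", 3, "SER"), ("B", 4, "GLU"),
                           CRIT, "sidechain")
        assert got is expected

    def test_hbond_angle_fail_at_45_degrees(self):
        s45 = 0.30 * np.sin(np.radians(45))
        c45 = 0.30 * np.cos(np.radians(45))
        traj = build_trajectory(
            [
                ("A", 3, "SER", "OG"), ("A", 3, "SER", "HG"),
                ("B", 4, "GLU", "OE1"),
            ],
            [[[0, 0, 0], [0.1, 0, 0], [c45, s45, 0]]],
        )
        assert not detect_hbond(traj.frames[0], ("A", 3, "SER"),
                                ("B", 4, "GLU"), CRIT, "sidechain")

    def test_hbond_no_donor_hydrogens_returns_false(self):
        traj = build_trajectory(
            [("A", 4, "LEU", "CA"), ("B", 4, "GLU", "OE1")],
            [[[0, 0, 0], [0.29, 0, 0]]],
        )
        assert not detect_hbond(traj.frames[0], ("A", 4, "LEU"),
                                ("B", 4, "GLU"), CRIT, "sidechain")

    @pytest.mark.parametrize(
        "d,expected", [(0.29, True), (0.32, True), (0.33, False)]
    )
    def test_catalytic_frame_boundary(self, d, expected):
        traj = build_trajectory(
            [("A", 999, "ZN", "ZN"), ("B", 3, "ALY", "OH")],
            [[[0, 0, 0], [0, 0, d]]],
        )
        assert is_catalytic_frame(traj.frames[0], CRIT) is expected


class TestDetectorsAgainstBruteForce:
    """Every detector must agree with the exhaustive oracle on random frames."""

    N_FRAMES = 400  # × the enzyme-residue/position grid ⇒ thousands of cases

    def test_scan_matches_oracle(self):
        traj = random_complex(seed=11, n_frames=self.N_FRAMES)
        records = {r.key: r.occurrence for r in scan_interactions(traj, CRIT)}
        enzyme = traj.enzyme_residues()
        positions = traj.substrate_offsets()
        checked = 0
        for f in range(traj.n_frames):
            residues = frame_residues(traj, f)
            for enz in enzyme:
                res_e = residues[("A", enz[1])]
                for pos in positions:
                    sub = traj.substrate_residue(pos)
                    res_s = residues[("B", sub[1])]
                    expected = {
                        "contact": contact_bruteforce(res_e, res_s),
                        "ionic": ionic_bruteforce(res_e, res_s),
                        "hbond_sidechain": hbond_sidechain_bruteforce(
                            res_e, res_s
                        ),
                        "hbond_to_backbone": hbond_backbone_bruteforce(
                            res_e, res_s
                        ),
                    }
                    for itype, want in expected.items():
                        key = (enz, pos, itype)
                        got = bool(records[key][f]) if key in records else False
                        assert got == want, (f, key)
                        checked += 1
        assert checked >= 1000


def make_record(percent_or_occ, n_frames=1000, catalytic=None, key=("R", 1, "contact")):
    if isinstance(percent_or_occ, (int, float)):
        k = int(round(percent_or_occ / 100 * n_frames))
        occ = np.zeros(n_frames, dtype=bool)
        occ[:k] = True
    else:
        occ = np.asarray(percent_or_occ, dtype=bool)
        n_frames = occ.size
    if catalytic is None:
        catalytic = np.ones(n_frames, dtype=bool)
    enz = ("A", 10, key[0])
    return InteractionRecord(enz, key[1], key[2], occ, catalytic)


class TestAggregation:
    def test_replicate_mean(self):
        reps = [[make_record(p)] for p in (10, 12, 8, 11, 9)]
        table = aggregate_frequencies(reps)
        assert list(table.entries.values()) == [10]

    def test_truncation_is_floor(self):
        reps = [[make_record(p)] for p in (1.7, 0.2, 0.9, 2.1, 0.8)]
        table = aggregate_frequencies(reps)
        (value,) = table.entries.values()
        assert value == 1
        (raw,) = table.raw_means.values()
        assert raw == pytest.approx(1.14)

    def test_sub_one_percent_dropped(self):
        reps = [[make_record(0.4)] for _ in range(5)]
        table = aggregate_frequencies(reps)
        assert table.entries == {}
        assert table.excluded == {}  # dropped, not excluded-with-reason

    def test_noncatalytic_only_excluded(self):
        occ = np.zeros(100, dtype=bool)
        occ[:30] = True
        cat = ~occ  # catalytic pose only when the interaction is absent
        reps = [[make_record(occ, catalytic=cat)] for _ in range(5)]
        table = aggregate_frequencies(reps)
        assert table.entries == {}
        assert list(table.excluded.values()) == ["noncatalytic-only"]

    def test_single_catalytic_overlap_retains(self):
        occ = np.zeros(100, dtype=bool)
        occ[:30] = True
        cat = np.zeros(100, dtype=bool)
        cat[29] = True  # one overlapping frame in one replicate suffices
        reps = [[make_record(occ, catalytic=~occ)] for _ in range(4)]
        reps.append([make_record(occ, catalytic=cat)])
        table = aggregate_frequencies(reps)
        assert list(table.entries.values()) == [30]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        reps = [
            [make_record(rng.integers(0, 2, 200).astype(bool))]
            for _ in range(5)
        ]
        t1 = aggregate_frequencies(reps)
        t2 = aggregate_frequencies(reps[::-1])
        assert t1.entries == t2.entries

    def test_truncation_never_increases(self):
        rng = np.random.default_rng(6)
        reps = [
            [make_record(rng.integers(0, 2, 97).astype(bool))]
            for _ in range(3)
        ]
        table = aggregate_frequencies(reps)
        for key, value in table.entries.items():
            assert 1 <= value <= table.raw_means[key]

    def test_zero_frame_replicate_rejected(self):
        with pytest.raises(ArgumentError):
            aggregate_frequencies([[make_record(np.zeros(0, dtype=bool))]])

    def test_empty_input_rejected(self):
        with pytest.raises(ArgumentError):
            aggregate_frequencies([])


def _table(percent, key):
    t = FrequencyTable(replicate_count=5)
    if percent >= 1:
        t.entries[key] = int(percent)
    return t


class TestLowFrequencyFilter:
    KEY_CONTACT = (("A", 10, "LEU"), 1, "contact")
    KEY_IONIC = (("A", 20, "ASP"), 1, "ionic")

    def test_single_capable_peptide_retains(self):
        # ionic at +1 needs a cationic +1 residue: only FRKacRW qualifies
        peps = [PeptideSequence.parse(s) for s in
                ["FRKacRW"] + [f"FRKac{x}W" for x in "AEWY"]]
        tables = {p: _table(0, self.KEY_IONIC) for p in peps}
        tables[peps[0]] = _table(5, self.KEY_IONIC)
        out = apply_low_frequency_filter(tables)
        assert out[peps[0]].entries[self.KEY_IONIC] == 5

    def test_mean_below_threshold_excluded(self):
        # one peptide at 5% among ten capable ⇒ panel mean 0.5% < 1%
        peps = [PeptideSequence.parse(f"FRKac{x}{y}")
                for x in "AERWY" for y in "WA"]
        tables = {p: _table(0, self.KEY_CONTACT) for p in peps}
        tables[peps[0]] = _table(5, self.KEY_CONTACT)
        out = apply_low_frequency_filter(tables)
        assert self.KEY_CONTACT not in out[peps[0]].entries
        assert out[peps[0]].excluded[self.KEY_CONTACT] == "low-frequency"

    def test_one_strong_peptide_lifts_mean(self):
        peps = [PeptideSequence.parse(f"FRKac{x}{y}")
                for x in "AERWY" for y in "WA"]
        tables = {p: _table(0, self.KEY_CONTACT) for p in peps}
        tables[peps[0]] = _table(12, self.KEY_CONTACT)
        out = apply_low_frequency_filter(tables)  # mean 1.2 ≥ 1
        assert out[peps[0]].entries[self.KEY_CONTACT] == 12
        assert all(
            out[p].excluded.get(self.KEY_CONTACT) is None for p in peps
        )

    def test_excluded_reason_recorded(self):
        peps = [PeptideSequence.parse(f"FRKac{x}W") for x in "AERWY"]
        tables = {p: _table(1, self.KEY_CONTACT) for p in peps}
        for p in peps[1:]:
            tables[p] = _table(0, self.KEY_CONTACT)
        out = apply_low_frequency_filter(tables)  # mean 0.2 < 1
        assert out[peps[0]].excluded[self.KEY_CONTACT] == "low-frequency"


class TestOccupancy:
    def _records(self, masks):
        return [
            make_record(np.asarray(m, bool), key=(name, pos, "contact"))
            for (name, pos), m in masks.items()
        ]

    def test_constructed_fractions(self):
        n = 100
        p1 = np.zeros(n, bool)
        p2 = np.zeros(n, bool)
        p1[:59] = True          # +1 site occupied 59 frames
        p2[43:59] = True        # overlap 16 ⇒ dual 16, single 43+0
        records = [
            make_record(p1, key=("P273", 1, "contact")),
            make_record(p1, key=("M274", 1, "contact")),
            make_record(p1, key=("Y306", 1, "contact")),
            make_record(p2, key=("P273", 2, "contact")),
            make_record(p2, key=("M274", 2, "contact")),
        ]
        dual, single, none = compute_occupancy(
            records, {"P273", "M274", "Y306"}, {"P273", "M274"}
        )
        assert (dual, single, none) == pytest.approx((0.16, 0.43, 0.41))

    def test_requires_all_site_residues_simultaneously(self):
        n = 10
        a = np.ones(n, bool)
        b = np.zeros(n, bool)
        records = [
            make_record(a, key=("P273", 1, "contact")),
            make_record(b, key=("M274", 1, "contact")),
            make_record(a, key=("Y306", 1, "contact")),
            make_record(a, key=("P273", 2, "contact")),
            make_record(a, key=("M274", 2, "contact")),
        ]
        dual, single, none = compute_occupancy(
            records, {"P273", "M274", "Y306"}, {"P273", "M274"}
        )
        assert dual == 0.0 and single == 1.0  # only the +2 site occupied

    def test_no_contacts_gives_all_none(self):
        records = [make_record(np.zeros(50, bool), key=("P273", 1, "contact"))]
        assert compute_occupancy(records, {"P273"}, {"P273"}) == (0.0, 0.0, 1.0)

    def test_empty_site_definition_rejected(self):
        with pytest.raises(ArgumentError):
            compute_occupancy([make_record(10)], set(), {"M274"})

    def test_fractions_sum_to_one_exactly(self):
        rng = np.random.default_rng(8)
        records = [
            make_record(rng.integers(0, 2, 333).astype(bool),
                        key=(name, pos, "contact"))
            for name in ("P273", "M274", "Y306") for pos in (1, 2)
        ]
        dual, single, none = compute_occupancy(
            records, {"P273", "M274", "Y306"}, {"P273", "M274"}
        )
        assert dual + single + none == 1.0

    def test_markov_chain_stationary_recovery(self):
        rng = np.random.default_rng(42)
        n = 20000
        p1 = markov_chain(rng, n, 0.10, 0.10)  # stationary 0.5
        p2 = markov_chain(rng, n, 0.05, 0.15)  # stationary 0.25
        records = [
            make_record(p1, key=("P273", 1, "contact")),
            make_record(p2, key=("P273", 2, "contact")),
        ]
        dual, single, none = compute_occupancy(records, {"P273"}, {"P273"})
        # chains independent ⇒ dual ≈ 0.5·0.25 with 3σ slack on n_eff
        for got, want, (p_on, p_off) in [
            (dual, 0.125, (0.05, 0.15)),
        ]:
            rho = 1 - p_on - p_off
            n_eff = n * (1 - rho) / (1 + rho)
            sigma = np.sqrt(want * (1 - want) / n_eff)
            assert abs(got - want) < 3 * sigma


class TestScan:
    def test_planted_window_gives_exact_occurrences(self):
        # contact active exactly in frames 100–199 of 1000
        n = 1000
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 2] = 0.6
        coords[100:200, 1, 2] = 0.25
        traj = build_trajectory(
            [("A", 10, "LEU", "CA"), ("B", 4, "TRP", "CB")], coords
        )
        records = scan_interactions(traj, CRIT)
        contact = [r for r in records if r.itype == "contact"
                   and r.enzyme_residue[1] == 10]
        assert len(contact) == 1
        assert contact[0].occurrence.sum() == 100
        assert contact[0].occurrence[100] and not contact[0].occurrence[99]

    def test_distant_complex_yields_nothing(self):
        coords = np.array([[[0, 0, 0], [5, 5, 5]]], dtype=float)
        traj = build_trajectory(
            [("A", 10, "LEU", "CA"), ("B", 4, "TRP", "CB")], coords
        )
        assert scan_interactions(traj, CRIT) == []

    def test_ionic_pair_also_registers_contact(self):
        traj = build_trajectory(
            [
                ("A", 1, "ARG", "NH1"), ("A", 1, "ARG", "HH11"),
                ("B", 4, "GLU", "OE1"),
            ],
            [[[0, 0.1, 0], [0, 0, 0], [0, 0, 0.2]]],
        )
        itypes = {r.itype for r in scan_interactions(traj, CRIT)}
        assert {"ionic", "contact"} <= itypes
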