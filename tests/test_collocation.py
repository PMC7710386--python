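"""Genus aggregation, contingency counting and the six association measures."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patternblend.collocation import (
    MOTIFS,
    AnnotationTable,
    ContingencyCounts,
    aggregate_to_genus,
    association_measures,
    association_screen,
    build_annotation_table,
    pair_contingency,
    read_annotations,
    triple_contingency,
)


def make_table(rows):
    """rows: list of (species, genus, {motif: flag})"""
    recs = []
    for sp, gen, flags in rows:
        recs.append(
            {
                "species": sp,
                "genus": gen,
                "family": "F",
                "order": "O",
                **{m: flags.get(m, 0) for m in MOTIFS},
            }
        )
    return build_annotation_table(pd.DataFrame(recs))


class TestReadAndAggregate:
    def test_read_toy_file(self, tmp_path):
        p = tmp_path / "anno.tsv"
        header = "species\tgenus\tfamily\torder\t" + "\t".join(MOTIFS)
        lines = [
            "A a\tA\tF\tO\t" + "\t".join(["1"] + ["0"] * 10),
            "A b\tA\tF\tO\t" + "\t".join(["0"] * 11),
            "B a\tB\tF\tO\t" + "\t".join(["0"] * 10 + ["1"]),
        ]
        p.write_text(header + "\n" + "\n".join(lines) + "\n")
        t = read_annotations(p)
        assert t.n_species == 3

    def test_duplicate_species_collapse_by_or(self, tmp_path):
        p = tmp_path / "anno.tsv"
        header = "species\tgenus\tfamily\torder\t" + "\t".join(MOTIFS)
        lines = [
            "A a\tA\tF\tO\t" + "\t".join(["1"] + ["0"] * 10),
            "A a\tA\tF\tO\t" + "\t".join(["0"] * 11),
        ]
        p.write_text(header + "\n" + "\n".join(lines) + "\n")
        t = read_annotations(p)
        assert t.n_species == 1
        assert t.df["St-H"].iloc[0] == 1

    def test_nonbinary_flag_rejected(self):
        df = pd.DataFrame(
            [{"species": "A a", "genus": "A", "family": "F", "order": "O",
              **{m: 0 for m in MOTIFS}}]
        )
        df.loc[0, "Maze"] = 2
        with pytest.raises(ValueError, match="non-binary"):
            build_annotation_table(df)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "anno.csv"
        p.write_text("species,genus\nA a,A\n")
        with pytest.raises(ValueError, match="missing"):
            read_annotations(p)

    def test_genus_flag_is_or_over_species(self):
        t = make_table(
            [
                ("A a", "A", {"Maze": 1}),
                ("A b", "A", {"Maze": 0}),
                ("B a", "B", {}),
            ]
        )
        g = aggregate_to_genus(t)
        assert g.n_genera == 2
        assert g.df.loc["A", "Maze"] == 1
        assert g.df.loc["A", "n_species"] == 2
        assert g.df.loc["B", "n_species"] == 1

    def test_aggregation_idempotent(self):
        t = make_table(
            [
                ("A a", "A", {"Maze": 1, "Sp-D": 1}),
                ("A b", "A", {"Sp-L": 1}),
                ("B a", "B", {"Mono": 1}),
            ]
        )
        g1 = aggregate_to_genus(t)
        # re-feed the genus table as if each genus were a single species
        back = AnnotationTable(
            g1.df.reset_index()
            .rename(columns={"genus": "species"})
            .assign(genus=lambda d: d["species"], family="F", order="O")
        )
        g2 = aggregate_to_genus(back)
        assert (g1.df[MOTIFS].values == g2.df[MOTIFS].values).all()


class TestContingency:
    @pytest.fixture()
    def six_genera(self):
        # hand-countable: genera with (Sp-D, Maze) flags
        # A:(1,1) B:(1,1) C:(1,0) D:(0,1) E:(0,0) F:(0,0), all >= 2 species
        rows = []
        for name, spd, maze in [
            ("A", 1, 1), ("B", 1, 1), ("C", 1, 0), ("D", 0, 1), ("E", 0, 0), ("F", 0, 0)
        ]:
            rows.append((f"{name} a", name, {"Sp-D": spd}))
            rows.append((f"{name} b", name, {"Maze": maze}))
        return aggregate_to_genus(make_table(rows))

    def test_hand_counted_pair(self, six_genera):
        c = pair_contingency(six_genera, "Sp-D", "Maze")
        assert (c.O11, c.O10, c.O01, c.O00) == (2, 1, 1, 2)
        assert c.N == 6 and c.A1 == 3 and c.B1 == 3

    def test_swap_transposes_off_diagonal(self, six_genera):
        c = pair_contingency(six_genera, "Sp-D", "Maze")
        d = pair_contingency(six_genera, "Maze", "Sp-D")
        assert (d.O11, d.O00) == (c.O11, c.O00)
        assert (d.O10, d.O01) == (c.O01, c.O10)

    def test_min_species_filter_can_empty_the_table(self, six_genera):
        c = pair_contingency(six_genera, "Sp-D", "Maze", min_species=99)
        with pytest.raises(ValueError, match="empty"):
            association_measures(c)

    def test_same_motif_rejected(self, six_genera):
        with pytest.raises(ValueError):
            pair_contingency(six_genera, "Maze", "Maze")
        with pytest.raises(ValueError):
            triple_contingency(six_genera, ("Sp-D", "Sp-D"), "Maze")

    def test_triple_counts_and_min_species(self):
        # Maze only ever in genera carrying both spot motifs -> O10 = 0
        rows = []
        for name, spd, spl, maze in [
            ("A", 1, 1, 1), ("B", 1, 1, 1), ("C", 1, 0, 0), ("D", 0, 1, 0), ("E", 0, 0, 0)
        ]:
            for i, m in enumerate(["x", "y", "z"]):
                rows.append(
                    (f"{name} {m}", name, {"Sp-D": spd and i == 0, "Sp-L": spl and i == 1, "Maze": maze and i == 2})
                )
        g = aggregate_to_genus(make_table(rows))
        c = triple_contingency(g, ("Sp-D", "Sp-L"), "Maze")
        assert c.O10 == 0 and c.O11 == 2
        # two-species genera are excluded at min_species=3
        rows.append(("G x", "G", {"Maze": 1}))
        rows.append(("G y", "G", {"Maze": 0}))
        g2 = aggregate_to_genus(make_table(rows))
        assert triple_contingency(g2, ("Sp-D", "Sp-L"), "Maze").N == 5


def brute_force_measures(genus_flags_a, genus_flags_b):
    """Independent oracle: explicit genus enumeration with textbook formulas."""
    o11 = o10 = o01 = o00 = 0
    for a, b in zip(genus_flags_a, genus_flags_b):
        if a and b:
            o11 += 1
        elif a and not b:
            o10 += 1
        elif b:
            o01 += 1
        else:
            o00 += 1
    n = o11 + o10 + o01 + o00
    a1, b1 = o11 + o10, o11 + o01
    e = {
        (1, 1): a1 * b1 / n,
        (1, 0): a1 * (n - b1) / n,
        (0, 1): (n - a1) * b1 / n,
        (0, 0): (n - a1) * (n - b1) / n,
    }
    o = {(1, 1): o11, (1, 0): o10, (0, 1): o01, (0, 0): o00}
    ll = 2 * sum(o[k] * math.log(o[k] / e[k]) for k in o if o[k] > 0)
    return {
        "JI": o11 / (o10 + o01 + o11),
        "SDC": 2 * o11 / (a1 + b1),
        "SSI": o11 / min(a1, b1),
        "LL": ll,
        "T": (o11 - e[(1, 1)]) / math.sqrt(o11) if o11 else 0.0,
        "Z": (o11 - e[(1, 1)]) / math.sqrt(e[(1, 1)]),
    }


class TestAssociationMeasures:
    def test_worked_arithmetic_example(self):
        s = association_measures(ContingencyCounts(O11=3, O10=1, O01=2, O00=10))
        assert s.JI == pytest.approx(0.5)
        assert s.SDC == pytest.approx(6 / 9)
        assert s.SSI == pytest.approx(0.75)

    def test_independent_margins_score_zero(self):
        # O exactly equals E for all cells -> LL = T = Z = 0
        s = association_measures(ContingencyCounts(O11=4, O10=4, O01=4, O00=4))
        assert s.LL == pytest.approx(0.0, abs=1e-12)
        assert s.T == pytest.approx(0.0, abs=1e-12)
        assert s.Z == pytest.approx(0.0, abs=1e-12)

    def test_t_and_z_share_sign(self):
        s = association_measures(ContingencyCounts(O11=8, O10=1, O01=1, O00=10))
        assert s.T > 0 and s.Z > 0
        s2 = association_measures(ContingencyCounts(O11=1, O10=8, O01=8, O00=1))
        assert s2.T < 0 and s2.Z < 0

    def test_o11_zero_flags_t(self):
        s = association_measures(ContingencyCounts(O11=0, O10=3, O01=3, O00=10))
        assert s.t_undefined and s.T == 0.0

    def test_no_radical_variant(self):
        c = ContingencyCounts(O11=8, O10=1, O01=1, O00=10)
        s_rad = association_measures(c, radicals=True)
        s_no = association_measures(c, radicals=False)
        e11 = c.expected()["E11"]
        assert s_no.Z == pytest.approx((8 - e11) / e11)
        assert s_rad.Z == pytest.approx((8 - e11) / math.sqrt(e11))

    def test_oracle_equivalence_on_random_tables(self):
        # 1000 random small genus tables vs explicit enumeration
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(4, 40)
            a = rng.random(n) < rng.uniform(0.2, 0.8)
            b = rng.random(n) < rng.uniform(0.2, 0.8)
            if not (a.any() and b.any() and (a & b).sum() >= 0):
                continue
            ref = brute_force_measures(a, b)
            c = ContingencyCounts(
                O11=int((a & b).sum()),
                O10=int((a & ~b).sum()),
                O01=int((~a & b).sum()),
                O00=int((~a & ~b).sum()),
            )
            s = association_measures(c)
            for key, val in ref.items():
                assert getattr(s, key) == pytest.approx(val, abs=1e-12), key

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        o11=st.integers(0, 50),
        o10=st.integers(0, 50),
        o01=st.integers(0, 50),
        o00=st.integers(0, 50),
    )
    def test_bounds_and_ji_le_ssi(self, o11, o10, o01, o00):
        c = ContingencyCounts(O11=o11, O10=o10, O01=o01, O00=o00)
        if c.N == 0 or c.A1 == 0 or c.B1 == 0:
            return
        s = association_measures(c)
        assert 0.0 <= s.JI <= 1.0
        assert 0.0 <= s.SDC <= 1.0
        assert 0.0 <= s.SSI <= 1.0
        assert s.JI <= s.SSI + 1e-12
        assert s.LL >= -1e-9


class TestScreen:
    def test_pairwise_screen_shape_and_symmetry(self):
        rng = np.random.default_rng(0)
        rows = []
        for gi in range(60):
            for si in range(3):
                rows.append(
                    (f"G{gi} s{si}", f"G{gi}", {m: int(rng.random() < 0.3) for m in MOTIFS})
                )
        g = aggregate_to_genus(make_table(rows))
        scr = association_screen(g, "pairwise")
        assert len(scr) == 55  # 11 choose 2
        # symmetry: the screen's value matches the transposed contingency
        row = scr.iloc[0]
        c_ab = pair_contingency(g, row.motif_a, row.motif_b)
        c_ba = pair_contingency(g, row.motif_b, row.motif_a)
        assert association_measures(c_ab).Z == pytest.approx(association_measures(c_ba).Z)

    def test_triple_screen_has_nine_partners(self):
        rng = np.random.default_rng(1)
        rows = []
        for gi in range(80):
            for si in range(4):
                rows.append(
                    (f"G{gi} s{si}", f"G{gi}", {m: int(rng.random() < 0.3) for m in MOTIFS})
                )
        scr = association_screen(aggregate_to_genus(make_table(rows)), "triple")
        assert len(scr) == 9
        assert not scr.motif_b.isin(["Sp-D", "Sp-L"]).any()
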