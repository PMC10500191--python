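"""Packaged study fixtures: the 11-marker panel, the probands' sharing
pattern, the 27-carrier phenotype cohort and the literature cohort totals.

Marker cM/bp coordinates are *reconstructed*: the source study does not
publish them, only the span sizes, so positions here are synthetic stand-ins
chosen to reproduce the published spans exactly (D14S1047-D14S270 =
2.13 cM / 1.92 Mb; D14S1028-D14S983 = 6.54 cM / 4.14 Mb) with plausible
chromosome-14q24 physical coordinates. Likewise the genotype fixture is a
synthetic allele table constructed to reproduce the published per-marker
sharing pattern, and the phenotype fixture reconstructs per-individual flag
assignments consistent with every published total (27 carriers, 17 M/10 F,
TAAD 4, any-arterial 5, other cardiovascular 9, connective tissue 14,
unaffected 11; family sizes 10/6/1/7/3). Ages are carried only where the
study prints them.
"""

from __future__ import annotations

from .io import GeneticMap, GenotypeRecord, Marker, PhenotypeRecord

__all__ = [
    "MARKER_PANEL",
    "study_map",
    "study_genotypes",
    "study_cohort",
    "literature_cohort_counts",
]

# Panel order along 14q24 with reconstructed coordinates and the published
# heterozygosity range [0.63, 0.83] spread evenly (step 0.02).
#   name          cM      bp         het
MARKER_PANEL = (
    ("D14S1065",  0.00, 72_800_000, 0.63),
    ("D14S258",   1.50, 73_700_000, 0.65),
    ("D14S1028",  3.00, 74_500_000, 0.67),
    ("D14S1047",  5.00, 75_600_000, 0.69),
    ("D14S61",    5.90, 76_200_000, 0.71),
    ("D14S270",   7.13, 77_520_000, 0.73),
    ("D14S983",   9.54, 78_640_000, 0.75),
    ("D14S74",   11.00, 79_600_000, 0.77),
    ("D14S287",  12.50, 80_500_000, 0.79),
    ("D14S1037", 14.00, 81_400_000, 0.81),
    ("D14S1044", 15.50, 82_300_000, 0.83),
)

VARIANT_NAME = "TGFB3_c.787G>C"
VARIANT_CM = 6.10          # between D14S61 and D14S270 (reconstructed)
VARIANT_BP = 76_447_000


def study_map() -> GeneticMap:
    """The 11-marker panel around the TGFB3 p.(Asp263His) locus."""
    markers = tuple(Marker(n, "14", cm, bp, het) for n, cm, bp, het in MARKER_PANEL)
    return GeneticMap(markers, VARIANT_NAME, VARIANT_CM, VARIANT_BP)


# Per-marker sharing pattern of the probands (figure-shaped): shared at
# D14S1065, D14S258, D14S1047, D14S61, D14S270; discordant elsewhere.
_SHARED = {"D14S1065", "D14S258", "D14S1047", "D14S61", "D14S270"}

# At shared markers every carrier holds the founder allele; at discordant
# markers the first two carriers hold disjoint pairs so no allele is common.
_FOUNDER = {n: 150 + 2 * i for i, (n, _, _, _) in enumerate(MARKER_PANEL)}

_PARTNERS = (2, 0, -2, 4, 2, -4)      # offsets giving varied second alleles
_DISCORDANT = ((0, 2), (4, 6), (0, 4), (2, 6), (0, 2), (4, 6))


def study_genotypes() -> list[GenotypeRecord]:
    """Six genotyped carrier probands of five families (synthetic alleles
    reproducing the published sharing pattern)."""
    families = ["FAM1", "FAM2", "FAM3", "FAM4", "FAM5", "FAM1"]
    records = []
    for j in range(6):
        pairs = []
        for name, _, _, _ in MARKER_PANEL:
            f = _FOUNDER[name]
            if name in _SHARED:
                a, b = f, f + _PARTNERS[j]
            else:
                off = _DISCORDANT[j]
                a, b = f + 20 + off[0], f + 20 + off[1]
            pairs.append((min(a, b), max(a, b)))
        records.append(GenotypeRecord(f"P{j + 1}", families[j], True, tuple(pairs)))
    return records


def _pr(ind, fam, sex, age, taad=0, art=0, cv=0, ct=0, z=""):
    return PhenotypeRecord(
        individual_id=ind, family_id=fam, sex=sex, age=age,
        taad=bool(taad), arterial_other=bool(art),
        cardio_other=bool(cv), connective=bool(ct), reported_z=z,
    )


def study_cohort() -> list[PhenotypeRecord]:
    """The 27 variant carriers (reconstructed per-individual assignment)."""
    M, F = "male", "female"
    return [
        # Family 1 (10 carriers: 8 M / 2 F)
        _pr("II:8",  "FAM1", M, 64, cv=1, ct=1),          # HCM proband
        _pr("II:4",  "FAM1", M, 77, cv=1, ct=1),          # septal hypertrophy
        _pr("III:5", "FAM1", M, 49, cv=1, ct=1),          # concentric hypertrophy
        _pr("III:9", "FAM1", M, 36, ct=1, z="2.0"),
        _pr("II:10", "FAM1", M, None, art=1, cv=1, ct=1), # coronary disease
        _pr("III:2", "FAM1", F, None, cv=1, ct=1),        # mitral insufficiency
        _pr("III:7", "FAM1", M, None, cv=1, ct=1),        # VSD (surgery age 1)
        _pr("III:11", "FAM1", M, 7),
        _pr("IV:1",  "FAM1", M, None, ct=1),
        _pr("III:13", "FAM1", F, None, ct=1),
        # Family 2 (6 carriers: 3 M / 3 F)
        _pr("II:8",  "FAM2", M, 74, taad=1, cv=1, ct=1, z="5.2"),  # Bentall, BAV
        _pr("II:2",  "FAM2", M, 80, taad=1, cv=1, ct=1, z="2.1"),  # root 43 mm
        _pr("II:5",  "FAM2", F, 55, cv=1),                          # AF
        _pr("III:4", "FAM2", F, 44),
        _pr("III:5", "FAM2", F, 41, z="1.7"),
        _pr("III:7", "FAM2", M, None),
        # Family 3 (1 carrier)
        _pr("II:1",  "FAM3", M, 15, ct=1, z="0.0"),       # bifid uvula, scoliosis
        # Family 4 (7 carriers: 3 M / 4 F)
        _pr("III:6", "FAM4", M, 31, taad=1),              # type A dissection
        _pr("II:2",  "FAM4", M, 76),
        _pr("II:4",  "FAM4", F, None),
        _pr("III:2", "FAM4", F, None),
        _pr("III:8", "FAM4", F, None),
        _pr("IV:1",  "FAM4", M, 5),
        _pr("IV:2",  "FAM4", F, None),
        # Family 5 (3 carriers: 2 M / 1 F)
        _pr("III:2", "FAM5", F, 50, ct=1),                # inguinal hernia
        _pr("II:1",  "FAM5", M, 75, taad=1, ct=1, z="6.4"),  # ascending 44 mm
        _pr("IV:1",  "FAM5", M, 25),
    ]


def literature_cohort_counts() -> dict[str, int]:
    """Published totals over the 82 non-overlapping literature LDS5 patients."""
    return {
        "n": 82,
        "n_male": 46,
        "n_female": 36,
        "taad": 33,
        "arterial_any": 38,
        "connective": 76,
    }
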