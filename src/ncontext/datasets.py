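"""Curated worked-example data: published rat nerve-injury lincRNA pairs.

Thirty (lincRNA, protein-coding target) pairs reported for sciatic nerve (SN)
and dorsal root ganglion (DRG) after rat sciatic-nerve injury, each with the
printed boundary gap (bp) and the target's side relative to the lincRNA
locus.  The set mixes rat and mouse-reference lincRNA identifiers, as in the
original annotation.  Used to build a deterministic demonstration fixture in
which every pair is encoded at its published offset, plus distractor coding
genes beyond the neighbourhood window.
"""

from __future__ import annotations

from .annotation import AnnotationSet, GenomicFeature

__all__ = ["NERVE_INJURY_LINCRNA_PAIRS", "build_lincrna_pair_fixture"]

#: (tissue, lincRNA name, target gene name, side, boundary gap in bp)
NERVE_INJURY_LINCRNA_PAIRS: tuple[tuple[str, str, str, str, int], ...] = (
    ("SN", "RGD1562521", "Rgs22", "right", 274577),
    ("SN", "Rn50_X_0667.2", "Rgs18", "left", 217956),
    ("SN", "Gm26825", "Stim2", "left", 487168),
    ("SN", "Fam9b", "Vps13b", "left", 274577),
    ("SN", "Rn50_X_0711.1", "Creb1", "right", 116889),
    ("SN", "Ct55", "Edem3", "left", 84281),
    ("SN", "Rn50_14_0846.1", "Suco", "right", 242915),
    ("SN", "Rn50_13_0828.1", "Zfyve28", "left", 18891),
    ("SN", "Fam178b", "Ptchd1", "right", 253992),
    ("SN", "Rn50_13_0839.5", "Pof1b", "right", 145307),
    ("SN", "Rn50_7_1163.2", "Gpd1", "right", 699513),
    ("SN", "Ino80dos", "Rb1cc1", "right", 609632),
    ("SN", "RP23-61N4.3", "Gng11", "right", 602367),
    ("SN", "Gm26673", "Thsd7a", "right", 862550),
    ("SN", "Gm26827", "Peg3", "right", 413420),
    ("SN", "Gm20204", "Arhgef7", "right", 493494),
    ("SN", "Gm28933", "Rdh14", "right", 28368),
    ("SN", "Gm26723", "Rdh14", "right", 130201),
    ("SN", "Gm26819", "Klf6", "right", 1620120),
    ("SN", "Yam1", "Tfb1m", "right", 965615),
    ("SN", "Gm26823", "Cul2", "right", 303188),
    ("SN", "Gm4221", "Zeb1", "right", 416081),
    ("SN", "4731419I09Rik", "Hey1", "right", 771424),
    ("SN", "A530017D24Rik", "Ccm2", "right", 139918),
    ("SN", "1700086L19Rik", "Klhl29", "right", 2852122),
    ("SN", "C130071C03Rik", "Wdr37", "right", 85451),
    ("DRG", "1700020I14Rik", "Itga8", "right", 354118),
    ("DRG", "Rn50_X_0744.2", "Edem3", "left", 39848),
    ("DRG", "Rn50_13_0853.1", "Chm", "right", 974768),
    ("DRG", "Rn50_7_1164.1", "Lhfpl1", "left", 678582),
)

_LINC_LEN = 10_000
_TARGET_LEN = 5_000
_ANCHOR = 5_000_000  # lincRNA start on each fixture chromosome


def build_lincrna_pair_fixture(
    distractor_gap: int = 3_000_001,
    n_distractors_per_pair: int = 1,
    rng=None,
) -> tuple[AnnotationSet, dict[str, set[str]], dict[str, str]]:
    """Fixture annotation encoding every curated pair at its printed offset.

    Each pair sits on its own chromosome: the lincRNA locus at a fixed
    anchor, the target placed so its boundary gap equals the published
    distance, and ``n_distractors_per_pair`` additional coding genes at
    ``distractor_gap`` (beyond the 3 Mb window by default) on the opposite
    side.  All targets *and* distractors are treated as DE for the pair's
    tissue, so the window alone decides retention.  When ``rng`` (a numpy
    Generator) is given, each distractor's gap is jittered upward by up to
    1 Mb, still beyond the window.

    Returns (annotation, tissue → DE coding-gene ids, lincRNA id → tissue).
    """
    ann = AnnotationSet()
    deg_by_tissue: dict[str, set[str]] = {}
    linc_tissue: dict[str, str] = {}
    for idx, (tissue, linc_name, target_name, side, dist) in enumerate(
        NERVE_INJURY_LINCRNA_PAIRS, start=1
    ):
        chrom = f"fx{idx}"
        linc_id = f"LINC_{idx:02d}"
        target_id = f"TGT_{idx:02d}"
        linc = (_ANCHOR, _ANCHOR + _LINC_LEN - 1)
        if side == "right":
            tgt_start = linc[1] + dist
        else:
            tgt_start = linc[0] - dist - _TARGET_LEN + 1
        tgt = (tgt_start, tgt_start + _TARGET_LEN - 1)
        ann.add(
            GenomicFeature(linc_id, linc_name, chrom, linc[0], linc[1], "+", "lincRNA")
        )
        ann.add(
            GenomicFeature(
                target_id, target_name, chrom, tgt[0], tgt[1], "+", "protein_coding"
            )
        )
        deg = deg_by_tissue.setdefault(tissue, set())
        deg.add(target_id)
        linc_tissue[linc_id] = tissue
        # distractors beyond the window, on the side opposite the target
        for j in range(n_distractors_per_pair):
            d_id = f"DIS_{idx:02d}_{j + 1}"
            gap = distractor_gap + j * 10_000
            if rng is not None:
                gap += int(rng.integers(0, 1_000_000))
            if side == "right":
                d_start = linc[0] - gap - _TARGET_LEN + 1
            else:
                d_start = linc[1] + gap
            ann.add(
                GenomicFeature(
                    d_id,
                    d_id,
                    chrom,
                    d_start,
                    d_start + _TARGET_LEN - 1,
                    "+",
                    "protein_coding",
                )
            )
            deg.add(d_id)
    return ann, deg_by_tissue, linc_tissue
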