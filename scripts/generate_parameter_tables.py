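"""Dev-time generator for the packaged parameter YAMLs.

Run from the repo root:  python scripts/generate_parameter_tables.py
Writes src/toxta/data/{libraries,background_genes,promoters}.yaml.
The promoter file embeds the calibrated derepressed-P2 rate and the
double-deletion attenuation modifier computed by simulate.calibrate_promoters.
"""

import math
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import yaml

DATA = Path(__file__).resolve().parents[1] / "src" / "toxta" / "data"
DATA.mkdir(exist_ok=True)

# ---------------------------------------------------------------- libraries
libraries = {
    "read_length": 100,
    "min_fragment": 130,
    "batches": {
        "batch1": {"insert_mean_log": round(math.log(250), 4), "insert_sd_log": 0.25},
        "batch2": {"insert_mean_log": round(math.log(300), 4), "insert_sd_log": 0.22},
    },
    # expected cuts per kb of transcript; nonzero only where toxin is
    # expressible (toxT present) and antitoxin absent
    "cleavage_rate": {
        "dtoxA": {"0": 0.0, "10": 0.5, "30": 1.0, "100": 2.0},
    },
}
(DATA / "libraries.yaml").write_text(yaml.safe_dump(libraries, sort_keys=False))

# ---------------------------------------------------------- background genes
genes = []


def add(gene_id, length, regulon, operon_id, baseline, fold):
    genes.append(
        {
            "gene_id": gene_id,
            "length": length,
            "regulon": regulon,
            "operon_id": operon_id,
            "baseline": baseline,
            "fold_change": {0: fold[0], 10: fold[1], 30: fold[2], 100: fold[3]},
        }
    )


# Regulon fold-change profiles and baselines are balanced so total
# transcript mass is approximately conserved across the time course
# (induced competence output offset by ribosomal/tRNA shutdown), as in a
# real transcriptome; FPKM comparisons across timepoints are then stable.
CRP_S_FOLD = (1.0, 3.0, 20.0, 15.0)
CRP_N_FOLD = (1.0, 1.8, 3.0, 2.5)

# competence (CRP-S) operons
for op, members in {
    "comA": [("comA", 1200), ("comB", 900), ("comC", 700)],
    "comE": [("comE1", 800), ("comE2", 600)],
    "comF": [("comF", 1000)],
    "pilA": [("pilA", 450), ("pilB", 1400), ("pilC", 1100), ("pilD", 750)],
    "rec2": [("rec2", 2300)],
    "dprA": [("dprA", 1100)],
}.items():
    for gid, ln in members:
        add(gid, ln, "CRP-S", op, 4.0, CRP_S_FOLD)

# CRP-N genes (classic catabolite regulon; induced in MIV independent of Sxy)
for op, members in {
    "mglB": [("mglB", 1000), ("mglA", 1500)],
    "galK": [("galK", 1150)],
    "ppdD": [("ppdD", 450)],
    "cyaA": [("cyaA", 2500)],
    "fruAB": [("fruA", 1700), ("fruB", 950)],
    "nanE": [("nanE", 690)],
}.items():
    for gid, ln in members:
        add(gid, ln, "CRP-N", op, 25.0, CRP_N_FOLD)

# purR regulon (repressed on starvation)
for gid, ln in [("purE", 510), ("purK", 1080), ("purH", 1590), ("purM", 1040), ("purL", 2330), ("purF", 1520)]:
    add(gid, ln, "purR", "pur", 80.0, (1.0, 0.9, 0.5, 0.35))

# tryptophan biosynthesis
for gid, ln in [("trpA", 810), ("trpB", 1190), ("trpC", 1360), ("trpD", 1010), ("trpE", 1560)]:
    add(gid, ln, "trp", "trp", 45.0, (1.0, 1.3, 2.0, 2.4))

# tRNA clusters (short, high copy; decline in MIV)
for gid in ["trnQ", "trnK", "trnL", "trnV"]:
    add(gid, 210, "tRNA", gid, 500.0, (1.0, 0.85, 0.6, 0.5))

# ribosomal protein operons (shut down on starvation)
for op, members in {
    "rpsJ": [("rpsJ", 310), ("rplC", 630), ("rplD", 600), ("rplW", 300), ("rplB", 820)],
    "rpsM": [("rpsM", 360), ("rpsK", 390), ("rpsD", 620), ("rpoA", 990)],
    "rplM": [("rplM", 430)],
}.items():
    for gid, ln in members:
        add(gid, ln, "ribosomal", op, 400.0, (1.0, 0.8, 0.55, 0.45))

# topoisomerase / SOS / housekeeping controls: flat across time and genotypes
for gid, ln in [
    ("gyrA", 2640), ("gyrB", 2370), ("topA", 2590),
    ("lexA", 620), ("recA", 1070), ("recN", 1680), ("recX", 480), ("ruvA", 610), ("impA", 500),
    ("adk", 650), ("eno", 1300), ("gapdh", 1010), ("pgi", 1650), ("ftsZ", 1190),
    ("secA", 2720), ("rpoB", 4030), ("dnaK", 1930), ("groEL", 1640),
]:
    add(gid, ln, "other", gid, 70.0, (1.0, 1.0, 1.0, 1.0))

(DATA / "background_genes.yaml").write_text(yaml.safe_dump({"genes": genes}, sort_keys=False))
print(f"background genes: {len(genes)}")

# ------------------------------------------------------------- promoters
from toxta.reference import GENOTYPES, load_reference
from toxta.simulate import LibraryParams, calibrate_promoters

model = load_reference()
lib = LibraryParams(
    batch_id="batch1",
    insert_mean_log=libraries["batches"]["batch1"]["insert_mean_log"],
    insert_sd_log=libraries["batches"]["batch1"]["insert_sd_log"],
)
cal = calibrate_promoters(model, lib)
print("calibration:", cal)

promoters = {
    "crp_s_basal": 50.0,
    "crp_s_induction": {0: 1.0, 10: 1.5, 30: 10.0, 100: 10.0},
    "crp_s_genotype_modifier": {
        "wildtype": 1.0,
        "dtoxA": 1.0,
        "dtoxT": 1.0,
        # attenuation calibrated so interior (+100) coverage at t=30 is 1/3 of wildtype
        "dtoxTA": round(cal["dtoxTA_modifier"], 4),
        "dcrp": 1.0,
        "dsxy": 1.0,
    },
    "induction_blocked": ["dcrp", "dsxy"],
    "p2_rate": {
        "wildtype": 2.0,  # repressed by antitoxin
        "dtoxT": 2.0,  # repressed (P2 itself is deleted in this construct)
        "dcrp": 2.0,
        "dsxy": 2.0,
        # derepressed; calibrated so normalized toxT level at t=0 is 9x wildtype
        "dtoxA": round(cal["p2_derepressed"], 2),
        # attenuated alongside the CRP-S modifier
        "dtoxTA": round(cal["p2_dtoxTA"], 4),
    },
}
(DATA / "promoters.yaml").write_text(yaml.safe_dump(promoters, sort_keys=False))
print("wrote", DATA)
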