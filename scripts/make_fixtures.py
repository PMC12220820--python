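"""Generate the packaged synthetic stand-in fixtures.

Builds a 13-pathway pan-PCD gene-set GMT whose union is exactly 963 unique
genes, and a 68-gene panel spanning exactly 7 PCD types, seeded with real
mouse PCD genes and padded with clearly synthetic `Pcds####` symbols.
Deterministic; outputs are committed under src/thanatoset/data/.
"""

from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "thanatoset" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# Curated real mouse PCD genes and their pathway memberships.
REAL = {
    "apoptosis": [
        "Casp3", "Casp7", "Casp8", "Casp9", "Bax", "Bak1", "Bcl2", "Bcl2l1",
        "Bid", "Bad", "Apaf1", "Fas", "Faslg", "Tnf", "Tnfrsf1a", "Trp53",
        "Myc", "Atf3", "Stat6", "Xiap", "Diablo", "Cycs", "Mcl1",
    ],
    "necroptosis": [
        "Ripk1", "Ripk3", "Mlkl", "Zbp1", "Casp8", "Tnf", "Tnfrsf1b",
        "Tradd", "Fadd", "Pgam5",
    ],
    "pyroptosis": [
        "Gsdmd", "Gsdme", "Casp1", "Casp4", "Casp8", "Nlrp3", "Aim2",
        "Pycard", "Il1b", "Il18", "Nek7", "Tlr2", "Cd84",
    ],
    "ferroptosis": [
        "Gpx4", "Slc7a11", "Acsl4", "Alox5", "Alox15", "Ptgs2", "Tfrc",
        "Fth1", "Ftl1", "Ncoa4", "Hmox1", "Nfe2l2", "Sat1", "Lpcat3",
    ],
    "autophagy": [
        "Becn1", "Atg5", "Atg7", "Atg12", "Atg16l1", "Map1lc3b", "Sqstm1",
        "Ulk1", "Pik3c3", "Mtor", "Ambra1", "Wipi2", "Gabarapl1", "Lamp2",
    ],
    "lysosome_dependent_cell_death": [
        "Ctsl", "Ctsb", "Ctsd", "Lamp1", "Tfeb", "Cd68", "Mcoln1",
    ],
    "entotic_cell_death": [
        "Cdh1", "Ctnnb1", "Rhoa", "Rock1", "Rock2", "Myh9", "Cdc42",
    ],
    "netotic_cell_death": [
        "Padi4", "Elane", "Mpo", "Itgam", "Ncf1", "Cybb",
    ],
    "parthanatos": ["Parp1", "Aifm1", "Parg", "Endog", "Mif"],
    "immunogenic_cell_death": [
        "Calr", "Hmgb1", "Hsp90aa1", "Anxa1", "Tlr4", "P2rx7", "Cxcl10",
    ],
    "anoikis": ["Itgb1", "Itga5", "Ptk2", "Src", "Bcl2l11", "Egfr"],
    "oxeiptosis": ["Keap1", "Pgam5", "Aifm1", "Nfe2l2"],
    "alkaliptosis": ["Car9", "Nfkb1", "Ikbkb", "Rela"],
}

TYPES = list(REAL)
PANEL_TYPES = [
    "apoptosis", "necroptosis", "pyroptosis", "ferroptosis", "autophagy",
    "lysosome_dependent_cell_death", "entotic_cell_death",
]

# gene -> set of types for the real seeds
membership: dict[str, set[str]] = {}
for t, genes in REAL.items():
    for g in genes:
        membership.setdefault(g, set()).add(t)

UNION_TARGET = 963
n_real = len(membership)
n_filler = UNION_TARGET - n_real

# Per-type filler quotas, roughly echoing real pathway-size proportions.
quota = {
    "apoptosis": 215, "autophagy": 160, "ferroptosis": 130, "necroptosis": 75,
    "pyroptosis": 70, "lysosome_dependent_cell_death": 45,
    "immunogenic_cell_death": 40, "parthanatos": 30, "netotic_cell_death": 28,
    "anoikis": 25, "entotic_cell_death": 22, "oxeiptosis": 12, "alkaliptosis": 10,
}
assert sum(quota.values()) >= n_filler

fillers = [f"Pcds{i:04d}" for i in range(1, n_filler + 1)]
i = 0
for t in TYPES:
    for _ in range(quota[t]):
        if i >= n_filler:
            break
        membership.setdefault(fillers[i], set()).add(t)
        i += 1
assert len(membership) == UNION_TARGET, len(membership)

# Secondary memberships for every 6th filler -> pathway overlap (sums exceed union).
for j, g in enumerate(fillers):
    if j % 6 == 0:
        primary = next(iter(membership[g]))
        alt = TYPES[(TYPES.index(primary) + 3) % len(TYPES)]
        membership[g].add(alt)

by_type: dict[str, list[str]] = {t: [] for t in TYPES}
for g in sorted(membership):
    for t in membership[g]:
        by_type[t].append(g)

desc = "synthetic stand-in pathway (curated seed genes + synthetic Pcds padding)"
with open(OUT / "pan_pcd_pathways.synthetic.gmt", "w") as fh:
    for t in TYPES:
        fh.write("\t".join([t, desc, *by_type[t]]) + "\n")

# 68-gene panel spanning exactly the 7 panel types.
named = [
    "Casp1", "Zbp1", "Ripk3", "Ctsl", "Alox5", "Cd84", "Myc", "Ripk1",
    "Stat6", "Gsdmd", "Casp8", "Cd68", "Fas", "Il1b", "Tnf", "Atf3",
]
for g in named:
    assert membership[g] <= set(PANEL_TYPES), (g, membership[g])

panel = list(named)
# Real padding restricted to genes whose full membership stays within the 7 types.
real_pad = [
    g for g in sorted(membership)
    if not g.startswith("Pcds") and g not in panel and membership[g] <= set(PANEL_TYPES)
]
panel += real_pad[: 68 - len(panel) - 20]
# Synthetic padding: fillers from the 7 panel types only.
syn_pad = [
    g for g in fillers
    if membership[g] <= set(PANEL_TYPES) and g not in panel
]
panel += syn_pad[: 68 - len(panel)]
assert len(panel) == 68, len(panel)
covered = set().union(*(membership[g] for g in panel))
assert covered == set(PANEL_TYPES), covered

with open(OUT / "thanatoset_panel.synthetic.tsv", "w") as fh:
    fh.write("gene\ttypes\tprovenance\n")
    for g in sorted(panel):
        fh.write(f"{g}\t{';'.join(sorted(membership[g]))}\tsynthetic stand-in panel\n")

print("catalog union:", len(membership))
print("panel:", len(panel), "types:", len(covered))
print("per-type sizes:", {t: len(v) for t, v in by_type.items()})
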