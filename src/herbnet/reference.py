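"""Transcribed reference fixtures: anti-RA drug panels and the top-15 herb table.

These are the literature-reported fixtures the pipeline is exercised
against: the two classes of Western anti-rheumatoid-arthritis reference
drugs (as named, including the ciclosporin/cyclosporine spelling-variant
pair counted separately in the source list), and the table of the fifteen
most frequently prescribed herbs with their traditional property and
accumulated/normalized frequencies. Drug target sets and fingerprints are
NOT part of the fixture — they are synthesized by :mod:`herbnet.synthetic`.
"""

from __future__ import annotations

#: Immunomodulatory anti-RA reference drugs (9 entries as listed).
IMMUNOMODULATORY_DRUGS: tuple[str, ...] = (
    "methotrexate",
    "leflunomide",
    "ciclosporin",
    "thalidomide",
    "cyclophosphamide",
    "azathioprine",
    "mycophenolate mofetil",
    "tacrolimus",
    "cyclosporine",
)

#: Hormone (glucocorticoid) anti-RA reference drugs (7 entries).
HORMONE_DRUGS: tuple[str, ...] = (
    "dexamethasone",
    "hydrocortisone",
    "cortisone",
    "triamcinolone",
    "prednisolone",
    "prednisone",
    "methylprednisolone",
)

#: Top 15 herbs of the prescription corpus:
#: (name, latin name, property, accumulated frequency, printed NF %).
TOP15_HERBS: tuple[tuple[str, str, str, int, float], ...] = (
    ("Ji Xue Teng", "Millettia reticulata", "Warm", 503, 5.10),
    ("Huo Xue Teng", "Sargentodoxa cuneata", "Neutral", 499, 5.06),
    ("Huang Qi", "Astragalus membranaceus", "Warm", 481, 4.87),
    ("Dang Gui", "Radix Angelicae sinensis", "Warm", 430, 4.36),
    ("Quan Xie", "Scorpio", "Neutral", 399, 4.04),
    ("Qing Feng Teng", "Caulis Sinomenii", "Neutral", 396, 4.01),
    ("Ku Shen", "Radix Sophorae flavescentis", "Cold", 323, 3.27),
    ("Wu Tou", "Aconitum carmichaeli", "Hot", 306, 3.10),
    ("Wu Gong", "Scolopendra", "Warm", 287, 2.91),
    ("Huang Bai", "Cortex Phellodendri", "Cold", 283, 2.87),
    ("Bi Xie", "Rhizoma Dioscoreae Hypoglaucae", "Neutral", 280, 2.84),
    ("Ren Dong Teng", "Caulis Lonicerae", "Cool", 257, 2.60),
    ("Qin Jiao", "Radix Gentianae macrophyllae", "Cold", 254, 2.57),
    ("Wu Shao She", "Zaocys dhumnades", "Neutral", 235, 2.38),
    ("Pu Gong Ying", "Taraxacum mongolicum", "Cold", 227, 2.30),
)

#: Total accumulated frequency consistent with every printed NF percentage
#: (the corpus total is not printed; this value reproduces all 15 rounded
#: percentages of the table).
TOTAL_AF_CONSISTENT: int = 9870
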