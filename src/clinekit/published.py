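"""Previously published cline estimates for the western-Atlantic green
crab (*Carcinus maenas*) contact zone.

Best-model ML cline centres and widths (km from the southern terminus at
Tuckerton, NJ) with two-log-likelihood support limits, per marker type
and sampling year, plus the 2014 cline position predicted by a neutral
advective-dispersal forecast. These printed estimates serve as inputs for
temporal rate-of-change arithmetic and coincidence/concordance
comparisons; they are not recomputed here (doing so requires the archived
genotype deposit).
"""

from __future__ import annotations

from clinekit.clines import PublishedCline

MICROSAT_CLINES = {
    2000: PublishedCline(1609, 619, (1531, 1675), (411, 947), "microsat 2000"),
    2002: PublishedCline(1544, 43, (1436, 1551), (21, 401), "microsat 2002"),
    2007: PublishedCline(1356, 694, (1252, 1448), (393, 955), "microsat 2007"),
    2015: PublishedCline(1244, 708, (1178, 1310), (562, 865), "microsat 2015"),
}

COI_CLINES = {
    2000: PublishedCline(1522, 481, (1467, 1574), (370, 638), "COI 2000"),
    2002: PublishedCline(1491, 395, (1438, 1523), (91, 606), "COI 2002"),
    2007: PublishedCline(1404, 1100, (1333, 1482), (868, 1387), "COI 2007"),
    2015: PublishedCline(1230, 849, (1168, 1298), (705, 1037), "COI 2015"),
}

#: neutral advective-model forecast of the COI cline for 2014
PREDICTED_2014 = PublishedCline(936, 828, (766, 1047), (400, 1294), "prediction 2014")

SNP_Q_CLINE = PublishedCline(1389, 925, (1355, 1418), (830, 1052), "SNP Q-value")
SNP_ALLELE_MEAN_CLINE = PublishedCline(1374, 1006, (1272, 1463), (701, 1442),
                                       "SNP allele-frequency mean")

#: multi-locus SNP-panel divergence between range ends (mean and range)
PANEL_END_TO_END_FST = 0.344
PANEL_END_TO_END_FST_RANGE = (0.071, 0.802)
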