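"""Exact coefficient tables for Poisson-lognormal moments.

For X ~ Poisson(L) with L lognormal of mean mu and squared coefficient of
variation v = c**2 (so E[L**r] = mu**r * (1+v)**(r*(r-1)/2)):

* ``STIRLING2[k][r]`` are Stirling numbers of the second kind, converting
  factorial moments to raw moments: E[X**k] = sum_r S(k,r) E[(X)_r].
* ``PLN_CENTRAL[m]`` maps each power a of mu to the integer coefficients
  (low order first) of a polynomial in v, such that the m-th central
  moment E[(X-mu)**m] = sum_a mu**a * poly_a(v).

The central-moment table is the symbolically expanded binomial sum; the
expansion is frozen here because evaluating the alternating raw-moment sum
in floating point loses ~m*log10(mu) digits to cancellation at high mu.
Regenerate with scripts/generate_pln_tables.py.
"""

MAX_ORDER = 10

STIRLING2 = {0: [1], 1: [0, 1], 2: [0, 1, 1], 3: [0, 1, 3, 1], 4: [0, 1, 7, 6, 1], 5: [0, 1, 15, 25, 10, 1], 6: [0, 1, 31, 90, 65, 15, 1], 7: [0, 1, 63, 301, 350, 140, 21, 1], 8: [0, 1, 127, 966, 1701, 1050, 266, 28, 1], 9: [0, 1, 255, 3025, 7770, 6951, 2646, 462, 36, 1], 10: [0, 1, 511, 9330, 34105, 42525, 22827, 5880, 750, 45, 1]}

PLN_CENTRAL = {
    2: {1: [1], 2: [0, 1]},
    3: {1: [1], 2: [0, 3], 3: [0, 0, 3, 1]},
    4: {1: [1], 2: [3, 7], 3: [0, 6, 18, 6], 4: [0, 0, 3, 16, 15, 6, 1]},
    5: {1: [1], 2: [10, 15], 3: [0, 40, 75, 25], 4: [0, 0, 60, 170, 150, 60, 10], 5: [0, 0, 0, 30, 135, 222, 205, 120, 45, 10, 1]},
    6: {1: [1], 2: [25, 31], 3: [15, 180, 270, 90], 4: [0, 45, 525, 1150, 975, 390, 65], 5: [0, 0, 45, 690, 2250, 3420, 3090, 1800, 675, 150, 15], 6: [0, 0, 0, 15, 330, 1581, 3760, 5715, 6165, 4945, 2997, 1365, 455, 105, 15, 1]},
    7: {1: [1], 2: [56, 63], 3: [105, 686, 903, 301], 4: [0, 525, 3360, 6370, 5250, 2100, 350], 5: [0, 0, 1050, 8225, 22575, 32550, 28945, 16800, 6300, 1400, 140], 6: [0, 0, 0, 945, 9765, 37863, 83265, 122535, 130410, 104055, 62958, 28665, 9555, 2205, 315, 21], 7: [0, 0, 0, 0, 315, 4410, 23604, 73755, 159390, 259105, 331716, 343161, 290745, 202755, 116175, 54257, 20349, 5985, 1330, 210, 21, 1]},
    8: {1: [1], 2: [119, 127], 3: [490, 2394, 2898, 966], 4: [105, 3850, 18291, 31612, 25515, 10206, 1701], 5: [0, 420, 12810, 72520, 178500, 247800, 217700, 126000, 47250, 10500, 1050], 6: [0, 0, 630, 21630, 155190, 527478, 1097950, 1577310, 1661310, 1320130, 797678, 363090, 121030, 27930, 3990, 266], 7: [0, 0, 0, 420, 18060, 167748, 766192, 2225160, 4635540, 7393400, 9371964, 9646728, 8153600, 5680080, 3253320, 1519224, 569772, 167580, 37240, 5880, 588, 28], 8: [0, 0, 0, 0, 105, 5880, 71078, 427260, 1657845, 4695040, 10385410, 18690672, 28083055, 35817180, 39186780, 37008076, 30258963, 21426300, 13112470, 6905220, 3107937, 1184032, 376740, 98280, 20475, 3276, 378, 28, 1]},
    9: {1: [1], 2: [246, 255], 3: [1918, 7932, 9075, 3025], 4: [1260, 22806, 90468, 146706, 116550, 46620, 7770], 5: [0, 7560, 115668, 538776, 1230075, 1659798, 1444401, 834120, 312795, 69510, 6951], 6: [0, 0, 18900, 314370, 1816290, 5640138, 11271330, 15893010, 16601760, 13148730, 7936488, 3611790, 1203930, 277830, 39690, 2646], 7: [0, 0, 0, 23940, 473760, 3449376, 14140938, 38920770, 78833790, 123864090, 155770650, 159686982, 134706390, 93761010, 53685450, 25067574, 9401238, 2765070, 614460, 97020, 9702, 462], 8: [0, 0, 0, 0, 15120, 370440, 3408552, 18036540, 65420460, 178349220, 385816536, 685217988, 1021456800, 1296717660, 1414906380, 1334243988, 1090055232, 771562260, 472096800, 248595480, 111886488, 42625188, 13562640, 3538080, 737100, 117936, 13608, 1008, 36], 9: [0, 0, 0, 0, 0, 3780, 116550, 1351980, 9078165, 42143500, 148524516, 420120792, 988425165, 1981126980, 3439432620, 5232876540, 7034808879, 8404444440, 8957075190, 8535342060, 7279899921, 5557246236, 3792906540, 2309905080, 1251493425, 600775812, 254183454, 94143028, 30260331, 8347680, 1947792, 376992, 58905, 7140, 630, 36, 1]},
    10: {1: [1], 2: [501, 511], 3: [6825, 25440, 27990, 9330], 4: [9450, 119595, 420825, 651850, 511575, 204630, 34105], 5: [945, 81900, 878535, 3592470, 7764750, 10250100, 8852550, 5103000, 1913625, 425250, 42525], 6: [0, 4725, 308700, 3539865, 17709930, 51492231, 99728580, 138550545, 143763795, 113554035, 68479971, 31158855, 10386285, 2396835, 342405, 22827], 7: [0, 0, 9450, 630000, 8366400, 51847740, 196520520, 519126300, 1028377350, 1596348600, 1994557950, 2037852180, 1716269100, 1193742900, 683329500, 319045860, 119652120, 35191800, 7820400, 1234800, 123480, 5880], 8: [0, 0, 0, 9450, 721350, 11491830, 88250820, 425827350, 1467225900, 3881960250, 8248713690, 14492426130, 21463806000, 27142753050, 29550415950, 27830932290, 22722303870, 16077984300, 9836187900, 5179204800, 2330981730, 888025380, 282555000, 73710000, 15356250, 2457000, 283500, 21000, 750], 9: [0, 0, 0, 0, 4725, 434700, 8443260, 80065800, 483120450, 2107734300, 7150946670, 19746515880, 45742869900, 90762487200, 156537873000, 237144807720, 317928052890, 379164183300, 403658444700, 384401127600, 327735353610, 250129362060, 170697747600, 103950151200, 56318125500, 27035058960, 11438272440, 4236437520, 1361714940, 375645600, 87650640, 16964640, 2650725, 321300, 28350, 1620, 45], 10: [0, 0, 0, 0, 0, 945, 107100, 2552130, 29735730, 221317765, 1197163134, 5066841780, 17577047670, 51558813495, 130699659510, 290866785714, 574914238965, 1018059257790, 1625723522290, 2352697996320, 3096931971231, 3718030006230, 4078769345100, 4093611890400, 3761139894525, 3163862924586, 2435820325470, 1714943063400, 1102766000535, 646542946170, 344847947664, 166867565040, 73005619995, 28759950345, 10150589610, 3190186926, 886163125, 215553195, 45379620, 8145060, 1221759, 148995, 14190, 990, 45, 1]},
}
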