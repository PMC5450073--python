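"""Published empirical amino-acid replacement models.

Lower-triangle exchangeabilities and equilibrium frequencies for the
JTT (Jones, Taylor & Thornton 1992), WAG (Whelan & Goldman 2001) and
LG (Le & Gascuel 2008) models, in the standard one-letter order
ARNDCQEGHILKMFPSTWYV.  Values are the canonical published constants.
"""

JTT_LOWER = [
    5.80e+01, 5.40e+01, 8.10e+01, 5.60e+01, 5.70e+01, 1.05e+02,
    1.79e+02, 2.70e+01, 3.60e+01, 3.00e+01, 3.50e+01, 5.40e+01,
    1.50e+01, 1.94e+02, 3.78e+02, 4.75e+02, 9.00e+00, 1.10e+01,
    2.98e+02, 4.50e+01, 1.60e+01, 1.13e+02, 3.10e+02, 2.90e+01,
    1.37e+02, 3.28e+02, 2.20e+01, 3.80e+01, 6.46e+02, 4.40e+01,
    5.00e+00, 7.40e+01, 1.01e+02, 6.40e+01, 1.26e+02, 2.00e+01,
    1.70e+01, 5.28e+02, 3.40e+01, 8.60e+01, 5.80e+01, 8.10e+01,
    3.91e+02, 4.70e+01, 1.20e+01, 2.63e+02, 3.00e+01, 1.00e+01,
    1.50e+01, 5.03e+02, 2.32e+02, 8.00e+00, 7.00e+01, 1.60e+01,
    1.00e+01, 4.90e+01, 7.67e+02, 1.30e+02, 1.12e+02, 1.10e+01,
    7.0e+00, 2.6e+01, 1.5e+01, 4.0e+00, 1.5e+01, 5.9e+01,
    3.8e+01, 4.0e+00, 4.6e+01, 3.1e+01, 9.0e+00, 5.0e+00,
    5.9e+01, 6.9e+01, 1.7e+01, 2.3e+01, 7.0e+00, 3.1e+01,
    7.80e+01, 1.40e+01, 2.23e+02, 4.20e+01, 1.15e+02, 2.09e+02,
    6.20e+01, 3.23e+02, 2.60e+01, 5.97e+02, 9.00e+00, 7.20e+01,
    2.92e+02, 4.30e+01, 4.00e+00, 1.64e+02, 5.30e+01, 5.10e+01,
    1.80e+01, 2.40e+01, 2.00e+01, 1.19e+02, 2.60e+01, 1.20e+01,
    9.00e+00, 1.81e+02, 1.80e+01, 5.00e+00, 1.80e+01, 3.00e+01,
    3.2e+01, 1.0e+01, 7.0e+00, 4.5e+01, 2.3e+01, 6.0e+00,
    6.00e+00, 2.70e+01, 1.40e+01, 5.00e+00, 2.40e+01, 2.01e+02,
    3.3e+01, 5.5e+01, 8.0e+00, 4.7e+01, 1.6e+01, 5.6e+01,
    4.50e+01, 3.30e+01, 4.00e+01, 1.15e+02, 7.30e+01, 4.60e+01,
    8.00e+00, 5.73e+02, 1.10e+01, 2.29e+02, 2.10e+01, 4.79e+02,
    8.90e+01, 1.00e+01, 4.00e+01, 2.45e+02, 9.00e+00, 3.20e+01,
    9.61e+02, 1.40e+01, 3.88e+02, 2.48e+02, 1.02e+02, 5.90e+01,
    2.5e+01, 5.2e+01, 2.4e+01, 1.8e+02, 6.5e+01, 4.0e+00,
    2.10e+01, 4.70e+01, 1.03e+02, 1.00e+01, 8.00e+00, 1.40e+01,
    4.30e+01, 1.60e+01, 2.90e+01, 2.26e+02, 2.40e+01, 1.80e+01,
    3.23e+02, 1.70e+01, 9.20e+01, 1.20e+01, 5.30e+01, 5.36e+02,
    6.20e+01, 2.85e+02, 1.18e+02, 6.00e+00, 1.00e+01, 2.30e+01,
    4.77e+02, 3.50e+01, 6.30e+01, 3.80e+01, 1.20e+01, 2.10e+01,
    1.12e+02, 7.10e+01, 2.50e+01, 1.60e+01,
]

JTT_FREQS = [
    7.6747923252076758e-02, 5.1690948309051694e-02, 4.2644957355042652e-02, 5.1543948456051550e-02, 1.9802980197019805e-02,
    4.0751959248040752e-02, 6.1829938170061841e-02, 7.3151926848073159e-02, 2.2943977056022944e-02, 5.3760946239053767e-02,
    9.1903908096091905e-02, 5.8675941324058678e-02, 2.3825976174023829e-02, 4.0125959874040135e-02, 5.0900949099050907e-02,
    6.8764931235068771e-02, 5.8564941435058568e-02, 1.4260985739014262e-02, 3.2101967898032102e-02, 6.6004933995066004e-02,
]

WAG_LOWER = [
    5.5157100000000003e-01, 5.0984799999999997e-01, 7.3899800000000004e-01, 1.0270400000000000e+00, 9.0859800000000002e-01, 1.5828500000000001e+00,
    1.4167200000000000e+00, 3.1695400000000001e-01, 1.9333500000000001e-01, 3.9791500000000002e-01, 9.0626499999999999e-01, 8.9349599999999996e-01,
    2.1049399999999999e-01, 1.4385500000000000e+00, 3.3707900000000000e+00, 2.1211099999999998e+00, 1.1313300000000000e-01, 2.4073500000000000e-01,
    2.0060099999999998e+00, 6.3534599999999997e-01, 1.4730399999999999e-01, 5.2819099999999997e-01, 3.0354999999999999e+00, 4.3915700000000002e-01,
    5.8466499999999999e-01, 2.1371500000000001e+00, 1.8697900000000001e-01, 4.9767099999999997e-01, 5.3514200000000001e+00, 6.8316200000000005e-01,
    1.0271100000000000e-01, 6.7948900000000001e-01, 1.2241899999999999e+00, 5.5441300000000004e-01, 1.1639200000000001e+00, 3.8153300000000001e-01,
    2.5184899999999999e-01, 5.4294200000000004e+00, 2.6525599999999999e-01, 1.5436399999999999e+00, 9.4719799999999998e-01, 1.1255599999999999e+00,
    3.9562900000000001e+00, 5.5423599999999995e-01, 1.3152800000000001e-01, 3.0120100000000001e+00, 1.9822100000000001e-01, 9.6162100000000000e-02,
    1.9508100000000000e-01, 3.9742299999999999e+00, 2.0300600000000002e+00, 7.1916700000000000e-02, 1.0860000000000001e+00, 1.9624600000000000e-01,
    3.0294900000000000e-02, 6.1678299999999997e-01, 6.1741599999999996e+00, 8.6558400000000002e-01, 9.3067599999999995e-01, 3.9437000000000000e-02,
    8.4804699999999997e-02, 4.7985499999999998e-01, 1.0375400000000000e-01, 4.6730399999999998e-02, 4.2398400000000003e-01, 1.0717600000000000e+00,
    3.7486599999999998e-01, 1.2976699999999999e-01, 3.2571099999999997e-01, 1.5233500000000000e-01, 9.8817900000000000e-02, 2.1351999999999999e-02,
    3.0667400000000000e-01, 2.4897200000000000e-01, 1.7013500000000001e-01, 3.8428699999999999e-01, 7.4033900000000000e-02, 3.9048200000000000e-01,
    3.9801999999999998e-01, 1.0940400000000000e-01, 1.4076599999999999e+00, 5.1298400000000000e-01, 7.1706999999999999e-01, 5.4383300000000001e-01,
    1.0021400000000000e+00, 5.4694700000000003e+00, 3.3005200000000001e-01, 4.2941099999999999e+00, 1.1391700000000000e-01, 8.6948899999999996e-01,
    3.8948999999999998e+00, 1.5452600000000001e+00, 9.9920800000000004e-02, 9.3337199999999998e-01, 1.0288700000000000e+00, 8.5792800000000002e-01,
    2.1573700000000001e-01, 2.2771000000000000e-01, 3.0128100000000002e-01, 5.6771700000000003e-01, 5.7002500000000000e-01, 1.2739500000000001e-01,
    1.5426300000000001e-01, 2.5844299999999998e+00, 3.1512400000000002e-01, 8.1133899999999995e-02, 6.8235500000000004e-01, 7.0493899999999998e-01,
    8.2276499999999997e-01, 1.5655700000000000e-01, 1.9630300000000001e-01, 5.8873100000000000e-01, 2.4940999999999999e-01, 3.0450100000000001e-02,
    6.1303700000000003e-02, 3.7355800000000000e-01, 1.7410000000000000e-01, 4.9931000000000003e-02, 2.4357000000000001e-01, 1.3418200000000000e+00,
    2.2583300000000001e-01, 3.3698299999999998e-01, 1.0360400000000000e-01, 1.8724700000000000e-01, 1.3819000000000001e-01, 4.9946200000000002e-01,
    8.9043200000000000e-01, 4.0414099999999997e-01, 6.7937099999999995e-01, 6.9619799999999998e-01, 7.4016899999999997e-01, 4.7330699999999998e-01,
    2.6256900000000000e-01, 3.8734400000000000e+00, 1.1835800000000000e-01, 3.1709700000000001e+00, 3.2383200000000001e-01, 4.2574600000000000e+00,
    1.0594699999999999e+00, 9.9928799999999998e-02, 3.1944000000000000e-01, 1.4581599999999999e+00, 2.1248300000000001e-01, 4.2016999999999999e-01,
    7.8212999999999999e+00, 2.5755499999999998e-01, 4.8540200000000002e+00, 2.1151700000000000e+00, 4.1584399999999999e-01, 3.4473900000000002e-01,
    3.2662200000000002e-01, 6.6530900000000004e-01, 3.9861799999999997e-01, 1.8003400000000001e+00, 9.3427600000000000e-01, 8.8835999999999998e-02,
    5.5689599999999995e-01, 9.6713000000000005e-01, 1.3869800000000001e+00, 1.3750499999999999e-01, 1.3326399999999999e-01, 3.0543399999999998e-01,
    1.1906300000000001e+00, 1.7132900000000001e-01, 4.9390499999999998e-01, 1.5161199999999999e+00, 5.1570600000000000e-01, 4.2843700000000001e-01,
    2.0584500000000001e+00, 1.6144400000000000e-01, 5.4593100000000006e-01, 1.7190300000000000e-01, 1.5296400000000001e+00, 6.4542799999999998e+00,
    6.4989200000000003e-01, 1.6132800000000000e+00, 7.9538399999999998e-01, 1.3940500000000000e-01, 2.1604599999999999e-01, 3.1488699999999997e-01,
    4.3780200000000002e+00, 5.2374200000000004e-01, 7.8699300000000005e-01, 2.3273900000000000e-01, 1.1086400000000000e-01, 2.9114800000000002e-01,
    1.3882300000000001e+00, 2.4853900000000002e+00, 3.6536900000000000e-01, 3.1473000000000001e-01,
]

WAG_FREQS = [
    8.6627908662790867e-02, 4.3972004397200441e-02, 3.9089403908940397e-02, 5.7045105704510574e-02, 1.9307801930780195e-02,
    3.6728103672810368e-02, 5.8058905805890577e-02, 8.3251808325180837e-02, 2.4431302443130246e-02, 4.8466004846600491e-02,
    8.6209008620900862e-02, 6.2028606202860624e-02, 1.9502701950270197e-02, 3.8431903843190382e-02, 4.5763104576310464e-02,
    6.9517906951790692e-02, 6.1012706101270617e-02, 1.4385901438590145e-02, 3.5274203527420354e-02, 7.0895607089560719e-02,
]

LG_LOWER = [
    4.2509300000000000e-01, 2.7681800000000001e-01, 3.9514400000000000e-01, 2.4890840000000001e+00, 9.6989400000000003e-01, 1.0385450000000001e+00,
    2.0660400000000001e+00, 3.5885800000000001e-01, 1.4982999999999999e-01, 3.9533699999999999e-01, 5.3651800000000005e-01, 1.1240349999999999e+00,
    2.5370100000000001e-01, 1.1776510000000000e+00, 4.7271820000000000e+00, 2.1395010000000001e+00, 1.8071699999999999e-01, 2.1895899999999999e-01,
    2.5478700000000001e+00, 7.5187800000000005e-01, 1.2395399999999999e-01, 5.3455100000000000e-01, 2.8079079999999998e+00, 3.6397000000000002e-01,
    3.9019199999999998e-01, 2.4266009999999998e+00, 1.2699099999999999e-01, 3.0184800000000001e-01, 6.3260670000000001e+00, 4.8413299999999998e-01,
    5.2721999999999998e-02, 3.3253300000000002e-01, 8.5815100000000000e-01, 5.7898700000000003e-01, 5.9360700000000000e-01, 3.1444000000000000e-01,
    1.7088700000000001e-01, 5.0761490000000000e+00, 5.2876800000000002e-01, 1.6957519999999999e+00, 5.4171199999999997e-01, 1.4376450000000001e+00,
    4.5092379999999999e+00, 1.9150300000000001e-01, 6.8427000000000002e-02, 2.1450779999999998e+00, 3.7100400000000000e-01, 8.9524999999999993e-02,
    1.6178699999999999e-01, 4.0083580000000003e+00, 2.0006789999999999e+00, 4.5376000000000000e-02, 6.1202500000000004e-01, 8.3687999999999999e-02,
    6.2556000000000000e-02, 5.2338600000000002e-01, 5.2438700000000003e+00, 8.4492599999999995e-01, 9.2711399999999999e-01, 1.0690000000000000e-02,
    1.5076000000000001e-02, 2.8295900000000002e-01, 2.5548000000000001e-02, 1.7416000000000001e-02, 3.9445599999999997e-01, 1.2402750000000000e+00,
    4.2586000000000002e-01, 2.9890000000000000e-02, 1.3510700000000000e-01, 3.7967000000000001e-02, 8.4807999999999995e-02, 3.4989999999999999e-03,
    5.6926500000000002e-01, 6.4054299999999997e-01, 3.2062700000000000e-01, 5.9400699999999995e-01, 1.3266000000000000e-02, 8.9368000000000003e-01,
    1.1052510000000000e+00, 7.5382000000000005e-02, 2.7844780000000000e+00, 1.1434800000000001e+00, 6.7012799999999995e-01, 1.1655320000000000e+00,
    1.9592909999999999e+00, 4.1285910000000001e+00, 2.6795900000000000e-01, 4.8135050000000001e+00, 7.2854000000000002e-02, 5.8245700000000000e-01,
    3.2342939999999998e+00, 1.6725690000000000e+00, 3.5854999999999998e-02, 6.2429400000000002e-01, 1.2238279999999999e+00, 1.0801360000000000e+00,
    2.3619899999999999e-01, 2.5733600000000001e-01, 2.1033199999999999e-01, 3.4884700000000002e-01, 4.2388100000000001e-01, 4.4264999999999999e-02,
    6.9672999999999999e-02, 1.8071770000000000e+00, 1.7373500000000000e-01, 1.8811000000000001e-02, 4.1940899999999998e-01, 6.1197299999999999e-01,
    6.0454500000000000e-01, 7.7852000000000005e-02, 1.2003700000000000e-01, 2.4503400000000000e-01, 3.1148399999999998e-01, 8.7049999999999992e-03,
    4.4261000000000002e-02, 2.9663600000000001e-01, 1.3953800000000000e-01, 8.9585999999999999e-02, 1.9696100000000000e-01, 1.7399899999999999e+00,
    1.2983600000000001e-01, 2.6849099999999998e-01, 5.4678999999999998e-02, 7.6701000000000005e-02, 1.0888200000000001e-01, 3.6631700000000000e-01,
    6.9726399999999999e-01, 4.4247199999999998e-01, 6.8213900000000005e-01, 5.0885100000000005e-01, 9.9001200000000000e-01, 5.8426199999999995e-01,
    5.9705399999999997e-01, 5.3068340000000003e+00, 1.1901299999999999e-01, 4.1450670000000001e+00, 1.5906899999999999e-01, 4.2736070000000002e+00,
    1.1127270000000000e+00, 7.8281000000000003e-02, 6.4104999999999995e-02, 1.0337390000000000e+00, 1.1166000000000000e-01, 2.3252300000000001e-01,
    1.0649107000000001e+01, 1.3750000000000001e-01, 6.3123579999999997e+00, 2.5926920000000000e+00, 2.4906000000000000e-01, 1.8228700000000000e-01,
    3.0293599999999998e-01, 6.1963199999999996e-01, 2.9964800000000003e-01, 1.7027450000000000e+00, 6.5660399999999997e-01, 2.3917999999999998e-02,
    3.9032200000000000e-01, 7.4868299999999999e-01, 1.1368630000000000e+00, 4.9905999999999999e-02, 1.3193199999999999e-01, 1.8520200000000001e-01,
    1.7988530000000000e+00, 9.9848999999999993e-02, 3.4695999999999999e-01, 2.0203660000000001e+00, 6.9617499999999999e-01, 4.8130600000000001e-01,
    1.8987179999999999e+00, 9.4464000000000006e-02, 3.6181900000000000e-01, 1.6500100000000001e-01, 2.4571209999999999e+00, 7.8039019999999999e+00,
    6.5468300000000001e-01, 1.3381320000000001e+00, 5.7146799999999998e-01, 9.5130999999999993e-02, 8.9612999999999998e-02, 2.9650100000000001e-01,
    6.4722790000000003e+00, 2.4886200000000000e-01, 4.0054699999999999e-01, 9.8368999999999998e-02, 1.4082500000000001e-01, 2.4584100000000000e-01,
    2.1881580000000000e+00, 3.1518150000000000e+00, 1.8951000000000001e-01, 2.4931300000000001e-01,
]

LG_FREQS = [
    7.9065920934079076e-02, 5.5940944059055940e-02, 4.1976958023041980e-02, 5.3051946948053055e-02, 1.2936987063012939e-02,
    4.0766959233040766e-02, 7.1585928414071590e-02, 5.7336942663057340e-02, 2.2354977645022357e-02, 6.2156937843062157e-02,
    9.9080900919099088e-02, 6.4599935400064604e-02, 2.2950977049022953e-02, 4.2301957698042306e-02, 4.4039955960044043e-02,
    6.1196938803061200e-02, 5.3286946713053292e-02, 1.2065987934012068e-02, 3.4154965845034156e-02, 6.9146930853069152e-02,
]

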