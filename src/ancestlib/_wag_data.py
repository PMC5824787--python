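"""Embedded WAG amino-acid substitution model data.

Exchangeabilities are the lower triangle (column-major) of the symmetric
WAG rate matrix in PAML amino-acid order (ARNDCQEGHILKMFPSTWYV), together
with the WAG equilibrium frequencies.  Values are the published
Whelan & Goldman (2001) estimates.
"""

PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"

# S[i, j] for j < i, column-major: (2,1), (3,1), ..., (20,1), (3,2), ...
WAG_LOWER_TRIANGLE = """
    0.551571000000000033 0.509847999999999968 0.738998000000000044 1.027039999999999953 0.908598000000000017 1.582850000000000090
    1.416719999999999979 0.316954000000000014 0.193335000000000007 0.397915000000000019 0.906264999999999987 0.893495999999999957
    0.210493999999999987 1.438549999999999995 3.370789999999999953 2.121109999999999829 0.113132999999999997 0.240735000000000005
    2.006009999999999849 0.635345999999999966 0.147303999999999991 0.528190999999999966 3.035499999999999865 0.439157000000000020
    0.584664999999999990 2.137150000000000105 0.186979000000000006 0.497670999999999975 5.351420000000000066 0.683162000000000047
    0.102710999999999997 0.679489000000000010 1.224189999999999889 0.554413000000000045 1.163920000000000066 0.381533000000000011
    0.251848999999999990 5.429420000000000357 0.265255999999999992 1.543639999999999901 0.947197999999999984 1.125559999999999894
    3.956290000000000084 0.554235999999999951 0.131528000000000006 3.012010000000000076 0.198221000000000008 0.096162100000000000
    0.195081000000000004 3.974229999999999929 2.030060000000000198 0.071916700000000000 1.086000000000000076 0.196246000000000004
    0.030294900000000000 0.616782999999999970 6.174159999999999648 0.865584000000000020 0.930675999999999948 0.039437000000000000
    0.084804699999999997 0.479854999999999976 0.103753999999999999 0.046730399999999998 0.423984000000000028 1.071760000000000046
    0.374865999999999977 0.129766999999999993 0.325710999999999973 0.152334999999999998 0.098817900000000000 0.021351999999999999
    0.306674000000000002 0.248971999999999999 0.170135000000000008 0.384286999999999990 0.074033900000000000 0.390481999999999996
    0.398019999999999985 0.109404000000000001 1.407659999999999911 0.512983999999999996 0.717069999999999985 0.543833000000000011
    1.002140000000000031 5.469470000000000276 0.330052000000000012 4.294109999999999872 0.113917000000000004 0.869488999999999956
    3.894899999999999807 1.545260000000000078 0.099920800000000004 0.933371999999999979 1.028869999999999951 0.857928000000000024
    0.215737000000000012 0.227709999999999996 0.301281000000000021 0.567717000000000027 0.570025000000000004 0.127395000000000008
    0.154263000000000011 2.584429999999999783 0.315124000000000015 0.081133899999999995 0.682355000000000045 0.704938999999999982
    0.822764999999999969 0.156557000000000002 0.196303000000000005 0.588731000000000004 0.249409999999999993 0.030450100000000001
    0.061303700000000003 0.373558000000000001 0.174100000000000005 0.049931000000000003 0.243570000000000009 1.341820000000000013
    0.225833000000000006 0.336982999999999977 0.103604000000000002 0.187246999999999997 0.138190000000000007 0.499462000000000017
    0.890432000000000001 0.404140999999999972 0.679370999999999947 0.696197999999999984 0.740168999999999966 0.473306999999999978
    0.262568999999999997 3.873439999999999994 0.118358000000000005 3.170970000000000066 0.323832000000000009 4.257460000000000022
    1.059469999999999912 0.099928799999999998 0.319440000000000002 1.458159999999999901 0.212483000000000005 0.420169999999999988
    7.821299999999999919 0.257554999999999978 4.854020000000000223 2.115169999999999995 0.415843999999999991 0.344739000000000018
    0.326622000000000023 0.665309000000000039 0.398617999999999972 1.800340000000000051 0.934275999999999995 0.088835999999999998
    0.556895999999999947 0.967130000000000045 1.386980000000000102 0.137504999999999988 0.133263999999999994 0.305433999999999983
    1.190630000000000077 0.171329000000000009 0.493904999999999983 1.516119999999999912 0.515705999999999998 0.428437000000000012
    2.058450000000000113 0.161444000000000004 0.545931000000000055 0.171903000000000000 1.529640000000000111 6.454279999999999795
    0.649892000000000025 1.613280000000000047 0.795383999999999980 0.139405000000000001 0.216045999999999988 0.314886999999999972
    4.378020000000000245 0.523742000000000041 0.786993000000000054 0.232739000000000001 0.110864000000000004 0.291148000000000018
    1.388230000000000075 2.485390000000000210 0.365368999999999999 0.314730000000000010
"""

WAG_FREQUENCIES = """
    0.086627908662790867 0.043972004397200441 0.039089403908940397 0.057045105704510574 0.019307801930780195 0.036728103672810368
    0.058058905805890577 0.083251808325180837 0.024431302443130246 0.048466004846600491 0.086209008620900862 0.062028606202860624
    0.019502701950270197 0.038431903843190382 0.045763104576310464 0.069517906951790692 0.061012706101270617 0.014385901438590145
    0.035274203527420354 0.070895607089560719
"""
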