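CYP1200A1
CYP1216A1
CYP1223A1
CYP1228A1
CYP1236A1
CYP1238A1
CYP1265A1
CYP1279A1
CYP1369A1
CYP1432A1
CYP1518A1
CYP1529A1
CYP1543A1
CYP1568A1
CYP159A1
CYP1607A1
CYP1658A1
CYP1759A1
CYP1810A1
CYP1832A1
CYP1866A1
CYP1896A1
CYP1920A1
CYP1929A1
CYP1931A1
CYP1940A1
CYP1941A1
CYP1943A1
CYP1972A1
CYP1984A1
CYP1994A1
CYP2076A1
CYP2080A1
CYP2134A1
CYP2180A1
CYP2349A1
CYP2427A1
CYP2723A1
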