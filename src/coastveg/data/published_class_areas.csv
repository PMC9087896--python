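season,date,blw_km2,l_fvc_km2,sl_fvc_km2,m_fvc_km2,h_fvc_km2,htz_km2,shtz_km2,mtz_km2,sltz_km2,ltz_km2
summer,2000.06,366.27,1130.73,1872.23,1178.33,1443.78,906.36,982.81,2619.26,657.43,825.51
summer,2005.06,611.89,1042.845,1462.21,1166.90,1802.48,785.27,1280.25,2657.49,561.73,801.60
summer,2009.07,1823.94,810.22,1090.41,1320.57,1116.84,952.79,737.38,2773.14,1087.06,611.91
summer,2015.07,617.73,1159.76,1379.00,1279.08,1750.11,1008.44,1008.75,2284.25,898.59,985.69
summer,2020.06,540.87,998.00,1394.44,1344.36,1908.04,907.56,1093.14,2479.23,899.82,805.97
winter,2000.12,508.29,1479.30,2026.24,1114.43,863.08,809.12,814.85,2338.86,1490.14,530.20
winter,2005.01,603.30,1717.48,1674.91,862.25,1228.40,522.25,1359.04,2993.18,542.83,669.12
winter,2010.12,722.36,1732.53,1807.00,800.94,1099.43,808.89,1238.82,2650.40,925.88,538.31
winter,2016.01,1197.54,2057.59,1534.55,652.84,743.18,824.99,1338.22,2504.20,764.66,735.65
winter,2020.12,948.63,844.41,1307.38,1259.15,1826.06,705.17,1017.44,3361.66,581.63,519.81
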