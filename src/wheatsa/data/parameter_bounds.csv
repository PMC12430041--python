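code,definition,unit,lower,upper
P1,potential daily grain filling rate during the grain filling period,g·grain-1·d-1,0.001,0.004
P2,potential daily grain filling rate from flowering to grain filling stage,g·grain-1·d-1,0.0005,0.0015
P3,daily potential grain nitrogen accumulation rate,g·grain-1·d-1,0.0000275,0.0000825
M1,lower limit of daily nitrogen accumulation rate in grains,g·grain-1·d-1,0.0000075,0.0000225
P4,crop photoperiod sensitivity index,dimensionless,0,5
V1,crop vernalization sensitivity index,dimensionless,0,5
G1,number of grains per unit stem,grain·g-1,10,40
M2,maximum grain weight per plant,g,0.02,0.06
T1,accumulated temperature from seedling to jointing stage,°C·d,200,600
T2,accumulated temperature from jointing to flowering period,°C·d,250,800
T3,accumulated temperature from flowering to grain filling period,°C·d,60,180
T4,accumulated temperature from grain filling to maturity,°C·d,200,900
K,extinction coefficient,dimensionless,0,1
R1,light energy utilization rate,g·MJ-1,1.116,1.364
Y1,maximum specific leaf area,mm2·g-1,22000,45000
I1,leaf area at the beginning of the plant,mm2,100,300
S1,slope of water stress in photosynthetic leaf aging,dimensionless,0.05,0.15
E1,crop water demand,dimensionless,0.75,2.25
N1,multiple effects of nitrogen deficiency on photosynthesis,dimensionless,0.75,2.25
I2,maximum leaf area index of aging caused by shading,m2·m-2,3.5,10.5
X1,daily average temperature affects the grouting rate,dimensionless,0,1
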