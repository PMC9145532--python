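ADAL
ADAR
ADEL
ADER
ADFL
ADFR
ADLL
ADLR
AFDL
AFDR
AIAL
AIAR
AIBL
AIBR
AIML
AIMR
AINL
AINR
AIYL
AIYR
AIZL
AIZR
ALA
ALML
ALMR
ALNL
ALNR
AQR
AS01
AS02
AS03
AS04
AS05
AS06
AS07
AS08
AS09
AS10
AS11
ASEL
ASER
ASGL
ASGR
ASHL
ASHR
ASIL
ASIR
ASJL
ASJR
ASKL
ASKR
AUAL
AUAR
AVAL
AVAR
AVBL
AVBR
AVDL
AVDR
AVEL
AVER
AVFL
AVFR
AVG
AVHL
AVHR
AVJL
AVJR
AVKL
AVKR
AVL
AVM
AWAL
AWAR
AWBL
AWBR
AWCL
AWCR
BAGL
BAGR
BDUL
BDUR
CANL
CANR
CEPDL
CEPDR
CEPVL
CEPVR
DA01
DA02
DA03
DA04
DA05
DA06
DA07
DA08
DA09
DB01
DB02
DB03
DB04
DB05
DB06
DB07
DD01
DD02
DD03
DD04
DD05
DD06
DVA
DVB
DVC
FLPL
FLPR
HSNL
HSNR
I1L
I1R
I2L
I2R
I3
I4
I5
I6
IL1DL
IL1DR
IL1L
IL1R
IL1VL
IL1VR
IL2DL
IL2DR
IL2L
IL2R
IL2VL
IL2VR
LUAL
LUAR
M1
M2L
M2R
M3L
M3R
M4
M5
MCL
MCR
MI
NSML
NSMR
OLLL
OLLR
OLQDL
OLQDR
OLQVL
OLQVR
PDA
PDB
PDEL
PDER
PHAL
PHAR
PHBL
PHBR
PHCL
PHCR
PLML
PLMR
PLNL
PLNR
PQR
PVCL
PVCR
PVDL
PVDR
PVM
PVNL
PVNR
PVPL
PVPR
PVQL
PVQR
PVR
PVT
PVWL
PVWR
RIAL
RIAR
RIBL
RIBR
RICL
RICR
RID
RIFL
RIFR
RIGL
RIGR
RIH
RIML
RIMR
RIPL
RIPR
RIR
RIS
RIVL
RIVR
RMDDL
RMDDR
RMDL
RMDR
RMDVL
RMDVR
RMED
RMEL
RMER
RMEV
RMFL
RMFR
RMGL
RMGR
RMHL
RMHR
SAADL
SAADR
SAAVL
SAAVR
SABD
SABVL
SABVR
SDQL
SDQR
SIADL
SIADR
SIAVL
SIAVR
SIBDL
SIBDR
SIBVL
SIBVR
SMBDL
SMBDR
SMBVL
SMBVR
SMDDL
SMDDR
SMDVL
SMDVR
URADL
URADR
URAVL
URAVR
URBL
URBR
URXL
URXR
URYDL
URYDR
URYVL
URYVR
VA01
VA02
VA03
VA04
VA05
VA06
VA07
VA08
VA09
VA10
VA11
VA12
VB01
VB02
VB03
VB04
VB05
VB06
VB07
VB08
VB09
VB10
VB11
VC01
VC02
VC03
VC04
VC05
VC06
VD01
VD02
VD03
VD04
VD05
VD06
VD07
VD08
VD09
VD10
VD11
VD12
VD13
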