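# SYNTHETIC stand-in catalog: literature-curated disease risk genes (144 symbols).
# Gene symbols SYNLIT* are synthetic filler; the rest are real risk-gene symbols.
TNF
IL6
TLR9
TLR3
TLR4
TGFB1
EIF2AK2
AGER
IL1B
CD40
TNFRSF11A
KRAS
INS
NTRK1
IL2
IL2RA
CXCL10
CCL4
FCGR1A
IFNG
SYNLIT001
SYNLIT002
SYNLIT003
SYNLIT004
SYNLIT005
SYNLIT006
SYNLIT007
SYNLIT008
SYNLIT009
SYNLIT010
SYNLIT011
SYNLIT012
SYNLIT013
SYNLIT014
SYNLIT015
SYNLIT016
SYNLIT017
SYNLIT018
SYNLIT019
SYNLIT020
SYNLIT021
SYNLIT022
SYNLIT023
SYNLIT024
SYNLIT025
SYNLIT026
SYNLIT027
SYNLIT028
SYNLIT029
SYNLIT030
SYNLIT031
SYNLIT032
SYNLIT033
SYNLIT034
SYNLIT035
SYNLIT036
SYNLIT037
SYNLIT038
SYNLIT039
SYNLIT040
SYNLIT041
SYNLIT042
SYNLIT043
SYNLIT044
SYNLIT045
SYNLIT046
SYNLIT047
SYNLIT048
SYNLIT049
SYNLIT050
SYNLIT051
SYNLIT052
SYNLIT053
SYNLIT054
SYNLIT055
SYNLIT056
SYNLIT057
SYNLIT058
SYNLIT059
SYNLIT060
SYNLIT061
SYNLIT062
SYNLIT063
SYNLIT064
SYNLIT065
SYNLIT066
SYNLIT067
SYNLIT068
SYNLIT069
SYNLIT070
SYNLIT071
SYNLIT072
SYNLIT073
SYNLIT074
SYNLIT075
SYNLIT076
SYNLIT077
SYNLIT078
SYNLIT079
SYNLIT080
SYNLIT081
SYNLIT082
SYNLIT083
SYNLIT084
SYNLIT085
SYNLIT086
SYNLIT087
SYNLIT088
SYNLIT089
SYNLIT090
SYNLIT091
SYNLIT092
SYNLIT093
SYNLIT094
SYNLIT095
SYNLIT096
SYNLIT097
SYNLIT098
SYNLIT099
SYNLIT100
SYNLIT101
SYNLIT102
SYNLIT103
SYNLIT104
SYNLIT105
SYNLIT106
SYNLIT107
SYNLIT108
SYNLIT109
SYNLIT110
SYNLIT111
SYNLIT112
SYNLIT113
SYNLIT114
SYNLIT115
SYNLIT116
SYNLIT117
SYNLIT118
SYNLIT119
SYNLIT120
SYNLIT121
SYNLIT122
SYNLIT123
SYNLIT124
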