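# SYNTHETIC stand-in catalog: database-derived disease risk genes (114 symbols).
SYNDB001
SYNDB002
SYNDB003
SYNDB004
SYNDB005
SYNDB006
SYNDB007
SYNDB008
SYNDB009
SYNDB010
SYNDB011
SYNDB012
SYNDB013
SYNDB014
SYNDB015
SYNDB016
SYNDB017
SYNDB018
SYNDB019
SYNDB020
SYNDB021
SYNDB022
SYNDB023
SYNDB024
SYNDB025
SYNDB026
SYNDB027
SYNDB028
SYNDB029
SYNDB030
SYNDB031
SYNDB032
SYNDB033
SYNDB034
SYNDB035
SYNDB036
SYNDB037
SYNDB038
SYNDB039
SYNDB040
SYNDB041
SYNDB042
SYNDB043
SYNDB044
SYNDB045
SYNDB046
SYNDB047
SYNDB048
SYNDB049
SYNDB050
SYNDB051
SYNDB052
SYNDB053
SYNDB054
SYNDB055
SYNDB056
SYNDB057
SYNDB058
SYNDB059
SYNDB060
SYNDB061
SYNDB062
SYNDB063
SYNDB064
SYNDB065
SYNDB066
SYNDB067
SYNDB068
SYNDB069
SYNDB070
SYNDB071
SYNDB072
SYNDB073
SYNDB074
SYNDB075
SYNDB076
SYNDB077
SYNDB078
SYNDB079
SYNDB080
SYNDB081
SYNDB082
SYNDB083
SYNDB084
SYNDB085
SYNDB086
SYNDB087
SYNDB088
SYNDB089
SYNDB090
SYNDB091
SYNDB092
SYNDB093
SYNDB094
SYNDB095
SYNDB096
SYNDB097
SYNDB098
SYNDB099
SYNDB100
SYNDB101
SYNDB102
SYNDB103
SYNDB104
SYNDB105
SYNDB106
SYNDB107
SYNDB108
SYNDB109
SYNDB110
SYNDB111
SYNDB112
SYNDB113
SYNDB114
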