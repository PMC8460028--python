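# Synthetic ribosomal-protein gene set (132 names) matching the synthetic gene map.
RPG001
RPG002
RPG003
RPG004
RPG005
RPG006
RPG007
RPG008
RPG009
RPG010
RPG011
RPG012
RPG013
RPG014
RPG015
RPG016
RPG017
RPG018
RPG019
RPG020
RPG021
RPG022
RPG023
RPG024
RPG025
RPG026
RPG027
RPG028
RPG029
RPG030
RPG031
RPG032
RPG033
RPG034
RPG035
RPG036
RPG037
RPG038
RPG039
RPG040
RPG041
RPG042
RPG043
RPG044
RPG045
RPG046
RPG047
RPG048
RPG049
RPG050
RPG051
RPG052
RPG053
RPG054
RPG055
RPG056
RPG057
RPG058
RPG059
RPG060
RPG061
RPG062
RPG063
RPG064
RPG065
RPG066
RPG067
RPG068
RPG069
RPG070
RPG071
RPG072
RPG073
RPG074
RPG075
RPG076
RPG077
RPG078
RPG079
RPG080
RPG081
RPG082
RPG083
RPG084
RPG085
RPG086
RPG087
RPG088
RPG089
RPG090
RPG091
RPG092
RPG093
RPG094
RPG095
RPG096
RPG097
RPG098
RPG099
RPG100
RPG101
RPG102
RPG103
RPG104
RPG105
RPG106
RPG107
RPG108
RPG109
RPG110
RPG111
RPG112
RPG113
RPG114
RPG115
RPG116
RPG117
RPG118
RPG119
RPG120
RPG121
RPG122
RPG123
RPG124
RPG125
RPG126
RPG127
RPG128
RPG129
RPG130
RPG131
RPG132
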