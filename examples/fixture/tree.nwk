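((((((sp0001:0.9616317797133163,sp0062:0.9616317797133163):1.3605382345567056,(((sp0017:1.387994777101469,(sp0042:1.0568214146513788,(sp0057:0.20927030118345247,sp0112:0.20927030118345247):0.8475511134679263):0.3311733624500901):0.6274929371826903,(sp0024:0.8820827763733385,sp0065:0.8820827763733385):1.1334049379108206):0.04838828727759559,((sp0021:0.5914591857325924,sp0084:0.5914591857325924):1.1320675159681692,sp0029:1.7235267017007616):0.34034929986099316):0.25829401270826713):0.13083759315862542,((sp0012:2.2766083543892455,(sp0018:1.7028718060405477,((sp0030:0.22283437256151828,sp0110:0.22283437256151828):1.1129708687094664,sp0047:1.3358052412709847):0.367066564769563):0.5737365483486978):0.07842329220351774,((((sp0014:0.41961401812723853,sp0096:0.41961401812723853):0.29360468871695833,(((sp0073:0.0498659971382418,sp0128:0.0498659971382418):0.09713813129072157,sp0117:0.14700412842896338):0.14103026610160896,(sp0104:0.024331493126388715,sp0131:0.024331493126388715):0.2637029014041836):0.4251843123136245):1.1047484061132749,(sp0027:1.3852907315143135,sp0043:1.3852907315143135):0.43267638144315823):0.36210354642951526,((sp0019:0.2119170886036894,(sp0111:0.1622183107698394,sp0116:0.1622183107698394):0.049698777833850016):0.5246159586053274,(sp0070:0.6264976015467418,sp0081:0.6264976015467418):0.11003544566227497):1.4435376121779702):0.17496098720577624):0.09797596083588411):1.9221398035275197,((((sp0005:0.05006146390485178,(sp0127:0.033978654967023125,sp0130:0.033978654967023125):0.016082808937828652):0.3292587095475312,sp0098:0.379320173452383):0.9313248671662135,(sp0048:0.08839882225208395,sp0122:0.08839882225208395):1.2222462183665126):2.7385142834058933,((((sp0006:0.6376110388792631,(sp0080:0.12373828574999379,sp0120:0.12373828574999379):0.5138727531292693):1.9126147778373221,((((((sp0011:0.35561007401051725,(sp0101:0.14370866854739006,sp0118:0.14370866854739006):0.2119014054631272):0.20271364176573137,sp0086:0.5583237157762486):0.02950172310525545,(sp0085:0.3698288054581296,sp0099:0.3698288054581296):0.2179966334233745):0.13673144693834427,sp0071:0.7245568858198483):0.8139099647802168,(sp0035:1.4169840175381383,sp0039:1.4169840175381383):0.12148283306192686):0.441408984779204,(((sp0025:0.014681548120731414,sp0132:0.014681548120731414):1.3637138428684281,(((sp0044:1.0148476590694857,sp0060:1.0148476590694857):0.05129397241804767,sp0056:1.0661416314875334):0.04304971799100077,(sp0053:1.0064285555767158,((sp0061:0.17921786397156314,sp0115:0.17921786397156314):0.7480211466925764,sp0064:0.9272390106641395):0.07918954491257635):0.1027627939018183):0.2692040415106254):0.06671597834242693,sp0037:1.4451113693315865):0.5347644660476827):0.5703499813373161):0.9842716848525481,(((((sp0008:0.3464381603737916,sp0102:0.3464381603737916):0.09607756102915488,sp0093:0.4425157214029465):0.5962924993056351,sp0059:1.0388082207085816):1.117672398502188,(sp0020:1.250642899728001,((sp0049:0.5163121098740948,(sp0088:0.011347231006581637,sp0133:0.011347231006581637):0.5049648788675132):0.12902468348299934,(sp0079:0.6047375713065639,(sp0082:0.12210244684833516,sp0121:0.12210244684833516):0.48263512445822876):0.04059922205053024):0.6053061063709069):0.9058377194827685):0.6206546639325063,((sp0010:1.6872489838965512,(sp0031:0.2083984729475441,sp0113:0.2083984729475441):1.478850510949007):0.07642905812811218,(sp0028:1.678717716852876,(sp0032:1.403241894184717,(sp0040:1.3689426154182995,(sp0045:0.7119892612450318,(sp0074:0.5399974216608623,(sp0087:0.0836835717733706,sp0123:0.0836835717733706):0.4563138498874917):0.17199183958416953):0.6569533541732677):0.03429927876641736):0.27547582266815906):0.08496032517178742):1.0134572411186125):0.7573622184258575):0.4023979970108179,((sp0007:2.3306281900335972,(sp0016:0.7649618440704655,sp0068:0.7649618440704655):1.5656663459631317):0.0024669465857125594,(sp0015:2.0484731790117263,(((sp0022:0.7999157740524185,((sp0067:0.723093533874144,((sp0072:0.07822847335384608,sp0124:0.07822847335384608):0.5798998437564311,sp0078:0.6581283171102772):0.0649652167638668):0.03427498294525533,(sp0069:0.6601374645792237,sp0077:0.6601374645792237):0.09723105224017559):0.04254725723301922):0.32554464682894535,((sp0052:0.43651758305330457,(sp0094:0.07338121130432373,sp0125:0.07338121130432373):0.36313637174898084):0.4914483238875782,sp0063:0.9279659069408828):0.19749451394048112):0.04972273014751272,sp0050:1.1751831510288766):0.8732900279828497):0.28462195760758346):1.6038003619606416):0.11226382544453861):0.3259880869316771):0.0005673316703070364,(sp0004:0.28540221302952595,sp0105:0.28540221302952595):4.0903125295969485):0.3465681728474732,((((sp0002:0.6682119797318089,sp0076:0.6682119797318089):0.9871987843396539,sp0033:1.6554107640714628):0.7268524242284733,(((((sp0013:0.13779692906700625,sp0119:0.13779692906700625):0.9587141612471228,sp0055:1.096511090314129):0.3405665308273922,sp0038:1.4370776211415213):0.4935113884818376,(sp0026:0.5058870064155423,sp0090:0.5058870064155423):1.4247020032078166):0.10830410480299069,(((sp0023:0.5991827130246392,(sp0083:0.36940615755958905,(sp0100:0.18522118129082532,sp0114:0.18522118129082532):0.18418497626876373):0.22977655546505016):0.09182675297958465,(sp0075:0.47446813570861135,((sp0091:0.28385466548606253,sp0106:0.28385466548606253):0.1184557898153642,(sp0097:0.3230881821423228,sp0103:0.3230881821423228):0.0792222731591039):0.07215768040718462):0.2165413302956125):0.7091185773279367,(((sp0041:0.510739992560791,(sp0089:0.43302859761023527,(sp0095:0.04094872798951066,sp0129:0.04094872798951066):0.3920798696207246):0.07771139495055568):0.5282759758330284,((sp0058:0.45465747223811004,sp0092:0.45465747223811004):0.3784191915924682,(sp0066:0.0684427691459275,sp0126:0.0684427691459275):0.7646338946846507):0.20593930456324117):0.058840995921552786,sp0054:1.0978569643153722):0.3022710790167884):0.638765071094189):0.34337007387358653):2.0000537751895564,(((sp0003:1.165045207699439,sp0051:1.165045207699439):0.440458059594135,sp0034:1.605503267293574):1.1717750992202376,((sp0009:1.3574944729959628,((sp0046:0.2552639787449653,sp0108:0.2552639787449653):0.007460997296914407,(sp0107:0.2488601562152617,sp0109:0.2488601562152617):0.013864819826618024):1.094769496954083):0.09060863609808889,sp0036:1.4481031090940517):1.32917525741976):1.6050385969756809):0.3399659519844548):0.0;
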