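code,lab_name,country
A,University of Arizona,USA
AA,University of Arizona AMS Laboratory,USA
AAR,Aarhus AMS Centre Aarhus University,Denmark
AECV,Alberta Environmental Centre Vegreville,Canada
ALG,Centre de Recherches Nucleaires d'Alger,Algeria
ANL,Argonne National Laboratory,USA
ANTW,University of Antwerp,Belgium
ANU,Australian National University,Australia
B,Universitaet Bern,Switzerland
BA,Peking University AMS Laboratory,China
BE,LARA Laboratory Universitaet Bern,Switzerland
BETA,Beta Analytic,USA
BGS,Brock University Geological Sciences,Canada
BIRM,University of Birmingham,United Kingdom
BK,Peking University,China
BLN,Berlin Radiocarbon Laboratory,Germany
BM,British Museum,United Kingdom
BONN,Universitaet Bonn,Germany
BS,Birbal Sahni Institute of Palaeobotany Lucknow,India
C,University of Chicago,USA
CAMS,Center for Accelerator Mass Spectrometry Lawrence Livermore,USA
CENA,Centro de Energia Nuclear na Agricultura Piracicaba,Brazil
CG,Institute of Geology Chinese Academy of Geological Sciences,China
CIRAM,CIRAM Laboratory Bordeaux,France
CNA,Centro Nacional de Aceleradores Seville,Spain
COL,CologneAMS Universitaet zu Koeln,Germany
CRL,Czech Radiocarbon Laboratory Prague,Czech Republic
CSIC,Consejo Superior de Investigaciones Cientificas Madrid,Spain
CURL,INSTAAR Laboratory for AMS Radiocarbon Preparation University of Colorado,USA
D,Trinity College Dublin,Ireland
DAK,IFAN Laboratory Dakar,Senegal
DEA,Institute for Nuclear Research Debrecen AMS,Hungary
DEB,Institute of Nuclear Research Debrecen,Hungary
DEM,NCSR Demokritos Athens,Greece
DIC,DICARB Radioisotopes Laboratory,USA
ENEA,ENEA Radiocarbon Laboratory Bologna,Italy
ERL,Universitaet Erlangen-Nuernberg,Germany
ETH,ETH Zurich AMS Laboratory,Switzerland
F,Universita di Firenze,Italy
FRA,Universitaet Frankfurt,Germany
FSU,Florida State University,USA
FTMC,Center for Physical Sciences and Technology Vilnius,Lithuania
FZ,Fortaleza Radiocarbon Laboratory,Brazil
GAK,Gakushuin University,Japan
GD,Silesian University of Technology Gliwice,Poland
GDA,Gliwice Absolute Dating Methods Centre AMS,Poland
GIF,Laboratoire des Sciences du Climat et de l'Environnement Gif-sur-Yvette,France
GIFA,Gif-sur-Yvette AMS Facility,France
GIN,Geological Institute Russian Academy of Sciences Moscow,Russia
GRA,Centre for Isotope Research Groningen AMS,Netherlands
GRM,Centre for Isotope Research Groningen MICADAS,Netherlands
GRN,Centre for Isotope Research Groningen,Netherlands
GSC,Geological Survey of Canada,Canada
GU,Scottish Universities Research and Reactor Centre Glasgow,United Kingdom
GX,Geochron Laboratories,USA
H,Heidelberg Radiocarbon Laboratory,Germany
HAR,AERE Harwell,United Kingdom
HD,Universitaet Heidelberg,Germany
HEL,University of Helsinki,Finland
HELA,Laboratory of Chronology Helsinki AMS,Finland
HV,Niedersaechsisches Landesamt fuer Bodenforschung Hannover,Germany
I,Teledyne Isotopes,USA
IAAA,Institute of Accelerator Analysis,Japan
ICA,International Chemical Analysis,USA
ICEN,Instituto Tecnologico e Nuclear Lisbon,Portugal
IGAN,Institute of Geography Russian Academy of Sciences Moscow,Russia
IRPA,Royal Institute for Cultural Heritage Brussels,Belgium
ISGS,Illinois State Geological Survey,USA
IVIC,Instituto Venezolano de Investigaciones Cientificas,Venezuela
K,National Museum of Denmark Copenhagen,Denmark
KEK,High Energy Accelerator Research Organization Tsukuba,Japan
KI,Universitaet Kiel,Germany
KIA,Leibniz-Labor Universitaet Kiel AMS,Germany
KIEV,Institute of Environmental Geochemistry Kyiv,Ukraine
KIK,Royal Institute for Cultural Heritage Brussels AMS,Belgium
KN,Universitaet zu Koeln,Germany
L,Lamont-Doherty Geological Observatory,USA
LACUFF,LAC-UFF Universidade Federal Fluminense,Brazil
LE,Institute for the History of Material Culture St Petersburg,Russia
LJ,Scripps Institution of Oceanography La Jolla,USA
LOD,Museum of Archaeology and Ethnography Lodz,Poland
LP,LATYR Universidad Nacional de La Plata,Argentina
LTL,CEDAD University of Salento Lecce,Italy
LU,Lund University,Sweden
LUA,Lund University Accelerator,Sweden
LUS,Lund University Single Stage AMS,Sweden
LV,Universite Catholique de Louvain,Belgium
LY,Universite Claude Bernard Lyon,France
LZ,Universitaet Leipzig,Germany
M,University of Michigan,USA
MAMS,Curt-Engelhorn-Zentrum Archaeometrie Mannheim,Germany
MC,Musee Oceanographique Monaco,Monaco
MTC,University of Tokyo AMS,Japan
N,Nishina Memorial Laboratory,Japan
NPL,National Physical Laboratory Teddington,United Kingdom
NOSAMS,National Ocean Sciences AMS Woods Hole,USA
NUTA,Nagoya University Tandetron,Japan
NZ,DSIR Institute of Nuclear Sciences,New Zealand
NZA,Rafter Radiocarbon Laboratory AMS,New Zealand
O,Humble Oil and Refining,USA
OS,NOSAMS Woods Hole Oceanographic Institution,USA
OWU,Ohio Wesleyan University,USA
OXA,Oxford Radiocarbon Accelerator Unit,United Kingdom
OZ,ANSTO Lucas Heights,Australia
P,University of Pennsylvania,USA
PITT,University of Pittsburgh,USA
PLD,Paleo Labo Company,Japan
POZ,Poznan Radiocarbon Laboratory,Poland
PRL,Physical Research Laboratory Ahmedabad,India
PSUAMS,Pennsylvania State University AMS,USA
PTA,CSIR Pretoria,South Africa
Q,University of Cambridge,United Kingdom
QL,Quaternary Isotope Laboratory University of Washington,USA
R,Universita di Roma La Sapienza,Italy
RICH,Royal Institute for Cultural Heritage AMS Brussels,Belgium
RIDDL,Simon Fraser University RIDDL,Canada
RL,Radiocarbon Ltd,USA
RT,Weizmann Institute of Science Rehovot,Israel
S,University of Saskatchewan,Canada
SAC,ITN Sacavem,Portugal
SACA,LMC14 ARTEMIS Saclay,France
SFU,Simon Fraser University,Canada
SI,Smithsonian Institution,USA
SMU,Southern Methodist University,USA
SNU,Seoul National University,South Korea
SOAN,Institute of Geology and Geophysics Novosibirsk,Russia
SRR,NERC Radiocarbon Laboratory East Kilbride,United Kingdom
ST,Stockholm Natural History Museum,Sweden
SU,Geological Survey of Finland,Finland
SUA,University of Sydney,Australia
SUERC,Scottish Universities Environmental Research Centre,United Kingdom
T,Radiological Dating Laboratory Trondheim,Norway
TA,Tartu University,Estonia
TF,Tata Institute of Fundamental Research,India
TK,University of Tokyo,Japan
TLN,Tallinn Institute of Geology,Estonia
TO,IsoTrace Laboratory University of Toronto,Canada
TRA,NTNU Trondheim AMS,Norway
TUA,Trondheim Uppsala AMS,Norway
TX,University of Texas at Austin,USA
U,Uppsala University,Sweden
UA,Angstrom Laboratory Uppsala University,Sweden
UB,Queen's University Belfast,United Kingdom
UBA,14CHRONO Centre Queen's University Belfast,United Kingdom
UBAR,Universitat de Barcelona,Spain
UCD,University College Dublin,Ireland
UCIAMS,Keck Carbon Cycle AMS University of California Irvine,USA
UCLA,University of California Los Angeles,USA
UCR,University of California Riverside,USA
UGA,Center for Applied Isotope Studies University of Georgia,USA
UGAMS,Center for Applied Isotope Studies University of Georgia AMS,USA
UGRA,Universidad de Granada,Spain
UM,University of Miami,USA
UNAM,Universidad Nacional Autonoma de Mexico,Mexico
UOC,A.E. Lalonde AMS Laboratory University of Ottawa,Canada
UQ,Universite du Quebec,Canada
USGS,US Geological Survey Menlo Park,USA
UTC,Van der Graaff Laboratory Utrecht,Netherlands
UZ,Universitaet Zuerich,Switzerland
VERA,Vienna Environmental Research Accelerator,Austria
VRI,Vienna Radium Institute,Austria
VS,Vilnius Radiocarbon Laboratory,Lithuania
W,US Geological Survey Washington,USA
WAT,University of Waterloo,Canada
WIS,University of Wisconsin,USA
WITS,University of the Witwatersrand,South Africa
WK,University of Waikato,New Zealand
WSU,Washington State University,USA
WW,US Geological Survey Reston,USA
XA,Xi'an AMS Center,China
Y,Yale University,USA
Z,Rudjer Boskovic Institute Zagreb,Croatia
ZK,Institute of Archaeology Chinese Academy of Social Sciences Beijing,China
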